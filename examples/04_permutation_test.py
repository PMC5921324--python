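"""Permutation test of grey-matter network differences between groups.

For each sparsity, group labels are reshuffled (group sizes preserved) and
the whole correlation-network pipeline is recomputed to build the null
distribution of the Cp and Lp group differences.
"""

import numpy as np

from dkinet import CohortConfig, generate_gm_cohort, gm_permutation_test

cfg = CohortConfig(seed=1, gm_effect=0.5)
tables, _ = generate_gm_cohort(cfg)
pat, ctl = tables["MK"]
grid = np.round(np.arange(0.06, 0.41, 0.04), 2)
res = gm_permutation_test(pat, ctl, grid, n_perm=200, seed=3, mode="weighted")

for attr in ("Cp", "Lp"):
    r = res[attr]
    print(f"{attr}: significant sparsity ranges (p < 0.05): "
          f"{r.significant_ranges}")
    k = len(grid) // 2
    print(f"  at S = {grid[k]:.2f}: patient {r.observed_a[k]:.3f}, "
          f"control {r.observed_b[k]:.3f}, p = {r.p[k]:.4f}")
print("\nDecreased clustering and increased path length in patients over "
      "most of the sweep is the degraded ('less optimal') small-world "
      "phenotype the generator injects with gm_effect = 0.5.")
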