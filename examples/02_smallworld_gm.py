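"""Small-world analysis of a grey-matter covariance network.

Builds the group-level mean-kurtosis correlation network of the synthetic
control cohort, thresholds it across the 6-40% sparsity range, and compares
clustering and path length against degree-preserving rewired null networks:
gamma = Cp/mean(Cp_rand), lambda = Lp/mean(Lp_rand), sigma = gamma/lambda.
"""

from dkinet import (
    CohortConfig,
    generate_gm_cohort,
    gm_correlation_matrix,
    small_worldness,
    sparsity_sweep,
)

cfg = CohortConfig(seed=1)
tables, _ = generate_gm_cohort(cfg)
corr = gm_correlation_matrix(tables["MK"][1])  # controls
print("sparsity   Cp     Lp    gamma  lambda  sigma")
for g in sparsity_sweep(corr, 0.06, 0.40, 0.04):
    r = small_worldness(g, n_rand=30, seed=7)
    print(f"  {g.sparsity:.2f}   {r.cp:.3f} {r.lp:6.3f}  {r.gamma:5.2f} "
          f"  {r.lam:5.2f}  {r.sigma:5.2f}")
print("\nsigma > 1 across the sweep marks small-world organization: "
      "much more clustering than matched random networks (gamma >> 1) at "
      "nearly random path lengths (lambda ~ 1).")
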