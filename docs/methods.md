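# Methods

This note documents the models, conventions and numerical choices behind
`dkinet`, in the order the pipeline applies them.

## Network construction

**GM covariance networks.** For one regional metric, entry (i, j) of the
group matrix is the Pearson correlation across subjects of region i's and
region j's values. The diagonal is forced to zero. A constant region column
(zero variance) has undefined correlations; these are set to 0 and a warning
names the region. Construction requires ≥3 subjects and ≥2 regions.

**WM weighted networks.** Per subject, an edge exists where the streamline
count (FN) is ≥ `fn_min` (default 1; the choice is exposed because
tractography false-positive suppression conventions vary). Every per-edge
metric layer (fiber length, FA, MD, Ad, RD, MK, AK, RK, KFA) is masked to
that common edge set, so all layers of one subject share a topology and
differ only in weights.

**Sparsity thresholding.** A matrix at sparsity S keeps the
K = floor(S·N(N−1)/2) strongest entries. Correlation matrices rank by |r| by
default (negative covariance is treated as connectivity, the convention of
the standard GM-covariance toolchain); a positive-only mode is available.
Ties at the cutoff break by lexicographic (i, j) order, which makes edge
sets reproducible and the sweep nested by construction. Weighted graphs
carry |r| (or the raw WM weight); binary graphs discard weights. K = 0 is an
error rather than an empty graph.

## Topology metrics

* **Clustering `Cp`**: fraction of a node's neighbor pairs that are
  connected; degree < 2 gives 0; `Cp` is the unweighted node mean. Weighted
  graphs use the Onnela geometric-mean triangle form (weights normalized by
  the graph maximum).
* **Path length `Lp`**: mean shortest-path distance over *connected* ordered
  pairs; weighted distances are 1/weight. Thresholded graphs at 6% sparsity
  are frequently disconnected, so the unreachable-pair count is carried in
  the result metadata rather than silently dropped. An all-disconnected
  graph is an error. (A largest-component mode would be the main
  alternative; finite-pair averaging was chosen because it uses all
  available structure and degrades gracefully along a sweep.)
* **Efficiency `Eg`, `Eloc`**: inverse-distance (Latora–Marchiori) means,
  with 1/∞ = 0; `Eloc` averages the efficiency of each node's
  neighbor-induced subgraph (0 for degree < 2). For weighted WM networks
  these are unbounded above 1, which is why streamline-count networks report
  `Lp` ≈ 0.1 and `Eloc` in the tens: they are 1/weight quantities, not hop
  counts.
* **Betweenness `Bi`**: pair-fraction shortest-path betweenness (Brandes,
  endpoints excluded), unnormalized; hub analysis divides by the network
  mean B̄, so any positive rescaling of `Bi` cancels.

Clustering and efficiencies are computed by dense adjacency algebra
(triangle counts via matrix powers, distances via `scipy.sparse.csgraph`)
because the permutation and calibration suites evaluate tens of thousands of
90-node graphs; equivalence with brute-force enumeration (Floyd–Warshall,
explicit path counting) is enforced by tests over every simple graph on ≤7
nodes and random weighted graphs on ≤12 nodes.

## Small-world analysis

Null networks preserve the exact degree sequence via double-edge swaps
(igraph C core, 10× edge-count swaps; an Erdős–Rényi same-size option
exists for strict "same nodes and edges" literalism). For weighted graphs
the topology is rewired and the observed weight multiset reassigned
randomly. Ensembles are seeded and reproducible; a graph with no valid swap
(e.g. a triangle) returns copies of itself with a warning.

γ = Cp/⟨Cp_rand⟩ and λ = Lp/⟨Lp_rand⟩ use the ensemble mean (default
`n_rand` 100); σ = γ/λ. σ > 1 is the primary small-world classifier; a
strict flag (γ > 1 and |λ−1| ≤ 0.25) is reported alongside. If the null
ensemble clustering collapses to zero, the result is flagged not-evaluable
instead of returning ∞.

Hubs: `bi = Bi/B̄ > 1.5`, strict inequality; table sorted by bi descending,
ties by label. Cortex classes (primary/association/paralimbic) are carried
as metadata only.

## Group statistics

* **GM permutation test**: observed Cp/Lp group differences per sparsity;
  per permutation, the pooled subjects are reallocated into groups of the
  original sizes (21/19) and the *entire* pipeline — correlation matrix,
  same-sparsity threshold, metrics — is recomputed. Two-tailed p with the
  +1 correction, p = (1 + #{|null| ≥ |obs|})/(n_perm + 1), so p is never 0.
  Default n_perm = 1000. Significant sparsities are reported as maximal
  contiguous runs with p < 0.05. The permutation stage defaults to
  *weighted* graphs (the thresholded matrix keeps |r| weights): group
  differences in covariance strength then contribute to Cp/Lp alongside
  topology, which is both the behavior of the standard toolchain's weighted
  option and vastly better powered at n = 40 than binary topology alone.
  Binary mode is a config switch.
* **ANCOVA** (WM attributes, per subject): `value ~ group + age + sex` by
  OLS with type-II partial F for the group term; with covariates omitted
  this reduces exactly to one-way ANOVA (F = t², test-enforced to 1e-10).
  Rank-deficient designs fail loudly, naming the collinear column.
* **Partial correlation**: Pearson correlation of OLS residuals after
  regressing both variables on the covariates; p from the t reference with
  n − k − 2 df. Zero residual variance (a variable exactly linear in the
  covariates) flags the result not-evaluable.
* **Demographics**: equal-variance two-sample t for continuous variables;
  chi-square for sex. For 2×2 tables the Yates continuity correction is
  used — with counts (12F/9M vs 9F/10M) it gives p ≈ 0.76 where the
  uncorrected test gives 0.54, matching the convention of clinical tables
  that report p ≈ 0.8 for such splits.
* **Normality**: one-sample Kolmogorov–Smirnov against a normal with the
  sample mean/SD, flagged as parameter-estimated (hence conservative);
  constant samples are flagged degenerate, not tested.
* **Multiplicity**: Benjamini–Hochberg by default across the metric columns
  within each attribute row (the printed-table layout); Bonferroni and
  identity available.

## Synthetic cohort generator

The generator defines the study conditions: 21 patients vs 19 controls, 90
regions, eight GM metrics plus FN/length, a single global seed from which
all sub-generators derive child streams (byte-identical regeneration).

**GM model.** The control latent network is a Watts–Strogatz graph (k = 6,
rewiring 0.1) — a genuine small-world ground truth. Control target
correlations decay geometrically with latent graph distance,
r(d) = r₀·ρ^(d−1) (r₀ = 0.6, ρ = 0.45), with a per-pair jitter shared
between groups, so thresholding recovers the latent graph at low sparsity
and proximity structure at higher sparsity.

The patient target is a `gm_effect`-weighted mixture of the control
structure with a *parity* structure: strong correlations only at odd ring
offsets, decaying with offset rank. Since odd ± odd is even, the top-K graph
of the parity structure is exactly triangle-free at every density, and its
slow spatial reach keeps paths long — mixing it in degrades clustering and
lengthens paths simultaneously, which is the empirical patient phenotype.
This design emerged from a negative result worth recording: with a fixed
edge count, every "local damage" perturbation we tried (edge deletion, edge
relocation, covariance scaling of within-neighborhood entries) moves Cp and
Lp in the *same* direction after thresholding, because lost local edges are
refilled by next-tier local entries (which re-create triangles) or by
background entries (which act as shortcuts). A triangle-suppressed target is
the clean way to decouple the two.

Both targets are made positive definite by order-preserving shrinkage
toward the identity (t·C + I with t < 1/|λ_min|, minimum eigenvalue floor
0.05), never by eigenvalue flooring, which would scramble the entry ranking
of strongly indefinite targets. A side effect is deliberate: the patient
mixture needs a stronger shrink, so patient correlations are also globally
weaker — reduced inter-regional coordination, the qualitative hallmark of
patient covariance matrices.

Observations are multivariate normal on the log scale (per-metric location
at conventional scales, e.g. MK ≈ 0.95, MD ≈ 0.9 μm²/ms; 10% log-sd),
exponentiated so all values are positive, with observation noise
(`noise_sd`, default 0.1) folded in on the log scale.

**WM model.** A denser Watts–Strogatz latent (k = 14, ≈15.7% density,
matching tractography network densities). Patients have an `wm_effect`
fraction of edges relocated to mid-range ring pairs and edge weights
attenuated by (1 − `wm_effect`). FN is 1 + negative-binomial (mean ≈ 30) on
latent edges, with a 0.5% false-edge rate at FN ∈ {1, 2}; per-edge metric
weights are metric-scale × shared edge jitter × subject factor × log-normal
noise. The subject factor couples weights to a per-subject integrity latent
(patients centered at −2, controls at 0) plus a nuisance scale, so cognition
associations are strong but not deterministic.

**Covariates.** Ages ≈ 74 ± 7 (patients) vs 70 ± 8 (controls); sex at
12F/9M vs 9F/10M proportions; MMSE = clip(28.2 + link·integrity + ε, 0, 30)
and MoCA analogously (link default 4.5), reproducing ≈ 19/28 (MMSE) and
≈ 15/28 (MoCA) group means.

**What the generator does *not* emulate**: spatially realistic anatomy
(the ring geometry is abstract), metric-specific covariance differences
(all metrics share one latent structure per group), scanner/site effects,
age dependence of the networks themselves, and non-Gaussian value
distributions beyond log-normality. Passing tests therefore demonstrate
correctness and calibration of the *analysis machinery* under a known
truth, not claims about any real cohort.

## Problem sizes and numerical choices

* Sparsity grid 6–40%, step 0.01 (35 points) in the pipeline; statistical
  test suites use a step-0.02 grid and n_perm = 100–200 with 50–200
  replicate experiments — sizes chosen to make Monte-Carlo intervals tight
  at desk scale.
* Null ensembles: n_rand = 100 (library default), 50 in the acceptance
  script, 20 in sanity suites.
* Permutation seeds, null-ensemble seeds and cohort seeds all derive from
  one run seed by fixed offsets; two equal-seed runs produce byte-identical
  artifact checksums (manifest-enforced).
* Matrix symmetry tolerance on input: 1e-8 silently symmetrized; larger
  asymmetry symmetrized by averaging with a warning. Correlations clipped
  to [−1, 1] after averaging.
* Degenerate inputs fail loudly: K = 0 thresholds, empty path sets,
  rank-deficient ANCOVA designs, p-values outside (0, 1].

## Known limitations

* Weighted small-world nulls randomize topology given degrees and then
  permute weights; weight–degree correlations of the original graph are not
  preserved.
* The finite-pair Lp convention makes Lp non-monotone under extreme
  fragmentation (excluding pairs can lower the mean); the unreachable-pair
  count is reported so users can spot this regime.
* The KS normality check uses estimated parameters without a Lilliefors
  correction and is therefore conservative; it mirrors common
  clinical-paper practice rather than best available methodology.
* Group-level GM networks yield one graph per group, so GM inference is
  permutation-based only; subject-level GM covariance variants
  (e.g. leave-one-out or regression-residual networks) are out of scope.
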