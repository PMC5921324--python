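"""Group-comparison statistics for network metrics.

* Permutation test for grey-matter (group-level) networks: group labels are
  shuffled preserving group sizes and the whole pipeline — correlation
  matrix, same-sparsity threshold, Cp/Lp — is recomputed per permutation.
* ANCOVA (metric ~ group + age + sex, type-II F for group) for per-subject
  white-matter network attributes.
* Partial correlation (residual Pearson) between network attributes and
  cognitive scores with age/sex regressed out.
* Demographics t / chi-square tests, Kolmogorov–Smirnov normality checks,
  and Benjamini–Hochberg / Bonferroni multiplicity control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .construct import RegionalMetricTable, gm_correlation_matrix, threshold_by_sparsity
from .metrics import characteristic_path_length, clustering_coefficient


# ---------------------------------------------------------------------------
# permutation test for GM correlation networks


@dataclass
class PermutationResult:
    """Per-sparsity observed group difference and permutation p-values."""

    attribute: str                    # "Cp" | "Lp"
    sparsities: np.ndarray
    observed_a: np.ndarray            # group A value per sparsity
    observed_b: np.ndarray
    observed_diff: np.ndarray         # A - B
    p: np.ndarray                     # two-tailed, +1-corrected
    n_perm: int
    seed: int | None
    significant_ranges: list[tuple[float, float]] = field(default_factory=list)


def _cp_lp_curve(
    values: np.ndarray,
    regions: list[str],
    sparsities: np.ndarray,
    mode: str,
    rank: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Cp and Lp across the sparsity grid for one subjects-x-regions block."""
    table = RegionalMetricTable(
        subject_ids=[f"s{i}" for i in range(values.shape[0])],
        groups=["x"] * values.shape[0],
        regions=regions, values=values,
    )
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        corr = gm_correlation_matrix(table)
    cps = np.empty(len(sparsities))
    lps = np.empty(len(sparsities))
    for k, s in enumerate(sparsities):
        g = threshold_by_sparsity(corr, float(s), mode=mode, rank=rank)
        cps[k] = clustering_coefficient(g)[1]
        lps[k] = characteristic_path_length(g)[0]
    return cps, lps


def _contiguous_ranges(
    sparsities: np.ndarray, sig: np.ndarray
) -> list[tuple[float, float]]:
    """Maximal contiguous runs of significant grid points."""
    ranges = []
    start = None
    for s, flag in zip(sparsities, sig):
        if flag and start is None:
            start = s
        elif not flag and start is not None:
            ranges.append((float(start), float(prev)))
            start = None
        prev = s
    if start is not None:
        ranges.append((float(start), float(sparsities[-1])))
    return ranges


def gm_permutation_test(
    table_a: RegionalMetricTable,
    table_b: RegionalMetricTable,
    sparsities: np.ndarray | list[float],
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "binary",
    rank: str = "abs",
    alpha: float = 0.05,
) -> dict[str, PermutationResult]:
    """Permutation test of Cp and Lp differences between two GM cohorts.

    For each permutation the pooled subjects are reallocated to two groups of
    the original sizes and the correlation-matrix -> threshold -> Cp/Lp
    pipeline is recomputed at every sparsity.  Two-tailed p-values use the
    +1 correction p = (1 + #{|null| >= |observed|}) / (n_perm + 1), so p is
    never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if table_a.regions != table_b.regions:
        raise ValueError("tables do not share region labels")
    n_a, n_b = table_a.n_subjects, table_b.n_subjects
    if n_a + n_b < 6:
        raise ValueError("need at least 6 subjects combined")
    sparsities = np.asarray(sparsities, dtype=float)
    pooled = np.vstack([table_a.values, table_b.values])
    regions = list(table_a.regions)

    cps_a, lps_a = _cp_lp_curve(table_a.values, regions, sparsities, mode, rank)
    cps_b, lps_b = _cp_lp_curve(table_b.values, regions, sparsities, mode, rank)
    obs = {"Cp": cps_a - cps_b, "Lp": lps_a - lps_b}

    rng = np.random.default_rng(seed)
    exceed = {"Cp": np.zeros(len(sparsities)), "Lp": np.zeros(len(sparsities))}
    for _ in range(n_perm):
        perm = rng.permutation(n_a + n_b)
        ca, la = _cp_lp_curve(pooled[perm[:n_a]], regions, sparsities, mode, rank)
        cb, lb = _cp_lp_curve(pooled[perm[n_a:]], regions, sparsities, mode, rank)
        exceed["Cp"] += np.abs(ca - cb) >= np.abs(obs["Cp"])
        exceed["Lp"] += np.abs(la - lb) >= np.abs(obs["Lp"])

    out = {}
    for attr, (va, vb) in (("Cp", (cps_a, cps_b)), ("Lp", (lps_a, lps_b))):
        p = (1.0 + exceed[attr]) / (n_perm + 1.0)
        out[attr] = PermutationResult(
            attribute=attr, sparsities=sparsities,
            observed_a=va, observed_b=vb, observed_diff=obs[attr],
            p=p, n_perm=n_perm, seed=seed,
            significant_ranges=_contiguous_ranges(sparsities, p < alpha),
        )
    return out


# ---------------------------------------------------------------------------
# ANCOVA


@dataclass
class AncovaResult:
    metric: str
    attribute: str
    f_statistic: float
    p: float
    adjusted_p: float | None
    covariates: tuple[str, ...]
    n: int


def ancova_group_effect(
    values: np.ndarray,
    group: np.ndarray | list,
    age: np.ndarray | None = None,
    sex: np.ndarray | list | None = None,
    metric: str = "",
    attribute: str = "",
) -> AncovaResult:
    """Type-II F test of the group effect, adjusting for age and sex.

    Fits value ~ group + age + sex by OLS and reports the partial (type-II)
    F and p for the group term.  With no covariates this reduces exactly to
    the one-way ANOVA F = t^2 of the pooled two-sample t-test.
    """
    import statsmodels.api as sm
    from statsmodels.stats.anova import anova_lm

    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    levels, counts = np.unique(group, return_counts=True)
    if len(levels) != 2 or counts.min() < 3:
        raise ValueError("need two groups with at least 3 subjects each")
    df = pd.DataFrame({"value": values, "group": group})
    terms = ["C(group)"]
    covs: list[str] = []
    if age is not None:
        df["age"] = np.asarray(age, dtype=float)
        terms.append("age")
        covs.append("age")
    if sex is not None:
        df["sex"] = np.asarray(sex)
        terms.append("C(sex)")
        covs.append("sex")
    import statsmodels.formula.api as smf

    model = smf.ols("value ~ " + " + ".join(terms), data=df)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name the offending column for the caller
        names = model.exog_names
        for k in range(1, exog.shape[1]):
            if np.linalg.matrix_rank(exog[:, : k + 1]) < k + 1:
                raise ValueError(f"rank-deficient design: column {names[k]!r} "
                                 "is collinear with earlier columns")
        raise ValueError("rank-deficient design matrix")
    fit = model.fit()
    tab = anova_lm(fit, typ=2)
    f = float(tab.loc["C(group)", "F"])
    p = float(tab.loc["C(group)", "PR(>F)"])
    return AncovaResult(metric=metric, attribute=attribute, f_statistic=f, p=p,
                        adjusted_p=None, covariates=tuple(covs), n=len(values))


# ---------------------------------------------------------------------------
# partial correlation


@dataclass
class PartialCorrelationResult:
    attribute: str
    score: str
    r: float
    p: float
    adjusted_p: float | None
    covariates: tuple[str, ...]
    n: int
    evaluable: bool = True


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    attribute: str = "",
    score: str = "",
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after regressing out covariates.

    p-values come from the t reference with n - k - 2 degrees of freedom
    (k = number of covariates).  With an empty covariate set this equals the
    plain Pearson correlation.  If either residual is (numerically)
    constant — e.g. y exactly linear in the covariates — the result is
    flagged not evaluable rather than returning a spurious r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    k = z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > k + 2 subjects")
    design = np.column_stack([np.ones(n), z])
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    tol = 1e-10
    if rx.std() <= tol * max(1.0, np.abs(x).max()) or \
            ry.std() <= tol * max(1.0, np.abs(y).max()):
        return PartialCorrelationResult(
            attribute=attribute, score=score, r=np.nan, p=np.nan,
            adjusted_p=None, covariates=tuple(f"z{i}" for i in range(k)),
            n=n, evaluable=False,
        )
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - k - 2
    r_clip = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_clip * np.sqrt(dof / (1.0 - r_clip**2))
    p = float(2 * sps.t.sf(abs(t), dof))
    return PartialCorrelationResult(
        attribute=attribute, score=score, r=r, p=p, adjusted_p=None,
        covariates=tuple(f"z{i}" for i in range(k)), n=n,
    )


# ---------------------------------------------------------------------------
# demographics, normality, multiplicity


def demographics_compare(covariates: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of demographic/cognitive variables.

    Continuous variables (age, MMSE, MoCA, ...) use the equal-variance
    two-sample t-test; sex uses the chi-square test on the 2x2 table (with
    Yates continuity correction).  Returns one row per variable with group
    mean (+/-SD) summaries, the statistic and p.
    """
    groups = covariates["group"].unique()
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    ga = covariates[covariates["group"] == groups[0]]
    gb = covariates[covariates["group"] == groups[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = []
    for col in covariates.columns:
        if col in ("subject_id", "group"):
            continue
        if col == "sex" or covariates[col].dtype == object:
            cats = sorted(covariates[col].unique())
            tab = np.array([[(g[col] == c).sum() for c in cats] for g in (ga, gb)])
            chi2, p, _, _ = sps.chi2_contingency(tab)
            rows.append({
                "variable": col,
                str(groups[0]): "/".join(str((ga[col] == c).sum()) for c in cats),
                str(groups[1]): "/".join(str((gb[col] == c).sum()) for c in cats),
                "test": "chi-square", "statistic": float(chi2), "p": float(p),
            })
        else:
            t, p = sps.ttest_ind(ga[col], gb[col], equal_var=True)
            rows.append({
                "variable": col,
                str(groups[0]): f"{ga[col].mean():.2f}(±{ga[col].std(ddof=1):.2f})",
                str(groups[1]): f"{gb[col].mean():.2f}(±{gb[col].std(ddof=1):.2f})",
                "test": "t", "statistic": float(t), "p": float(p),
            })
    return pd.DataFrame(rows)


def normality_check(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """One-sample Kolmogorov–Smirnov test against N(mean, SD) per group.

    Note: the reference normal uses the sample mean/SD, so p-values are
    conservative relative to a Lilliefors-corrected test; degenerate
    (constant) samples are flagged instead of tested.
    """
    rows = []
    for group, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 4:
            raise ValueError(f"group {group!r}: need n >= 4")
        sd = vals.std(ddof=1)
        if sd == 0:
            rows.append({"group": group, "n": vals.size, "statistic": np.nan,
                         "p": np.nan, "note": "degenerate (constant sample)"})
            continue
        stat, p = sps.kstest(vals, "norm", args=(vals.mean(), sd))
        rows.append({"group": group, "n": vals.size, "statistic": float(stat),
                     "p": float(p), "note": "parameters estimated from sample"})
    return pd.DataFrame(rows)


def adjust_pvalues(p: np.ndarray | list, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-comparison adjustment: 'fdr_bh' (default), 'bonferroni', 'none'."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "none":
        return p.copy()
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown method {method!r}")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method=method)[1]
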