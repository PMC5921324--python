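"""Synthetic two-group cohorts with known network ground truth.

Emulates the data behind a structural-covariance study of regional diffusion
kurtosis metrics: a patient group and a control group, each measured over 90
atlas regions, where the controls' inter-regional correlation structure is a
small-world (ring-lattice-plus-shortcuts) network and the patients' is a
degraded perturbation of it.  Also generates per-subject tractography-style
weighted connectivity matrices (streamline counts plus per-edge diffusion
metrics) and demographic/cognitive covariates tied to a per-subject
network-integrity factor, so every downstream stage of the pipeline is
testable without any imaging data.

Generative model
----------------
* Latent control network: Watts–Strogatz ring lattice on ``n_regions`` nodes
  (k=6 neighbors, rewiring probability 0.1) — a genuinely small-world truth.
* Control target covariance: correlations decay geometrically with latent
  graph distance, r(d) = r0 * rho^(d-1), with a per-pair jitter shared
  between groups.  Grading correlations by network proximity at every depth
  means the latent graph is recovered at low sparsity (shortcut edges
  included) and structure persists across the whole thresholding sweep.
* Patient target covariance: a ``gm_effect``-weighted mixture of the control
  structure with a triangle-suppressed "parity" structure (strong
  correlations only at odd ring offsets; odd +/- odd is even, so the
  thresholded parity graph is exactly triangle-free at every density, and
  its reach grows slowly, so paths stay long).  The mixture degrades
  clustering and lengthens paths simultaneously — the degraded small-world
  phenotype — and interpolates smoothly in ``gm_effect``.
* Both targets are made positive definite by order-preserving shrinkage
  toward the identity (t*C + I with t < 1/|lambda_min|), which keeps the
  entry ranking, hence the thresholded topology, exactly; the patient
  mixture needs a stronger shrink, so patient correlations are also globally
  weaker — the reduced inter-regional coordination seen in patient cohorts.
* Observations: multivariate normal on the log scale, exponentiated —
  regional metric values are strictly positive and correlations carry over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from .construct import ConnectivityMatrix, RegionalMetricTable

# independent child-stream tags derived from the single config seed
_S_LATENT, _S_GM_PERTURB, _S_WM_PERTURB, _S_GM_SAMPLE, _S_WM_SAMPLE = 0, 1, 2, 3, 4
_S_INTEGRITY, _S_COVARIATES, _S_JITTER, _S_WM_JITTER, _S_WM_LATENT = 5, 6, 7, 8, 9

GM_METRICS = ("MK", "AK", "RK", "KFA", "MD", "FA", "Ad", "RD")
WM_METRICS = ("FN", "length", "MK", "AK", "RK", "KFA", "MD", "FA", "Ad", "RD")

#: conventional regional scales (natural units) for each diffusion metric;
#: diffusivities in um^2/ms, length in mm.  These are config-exposed
#: conventions, not claims about any particular dataset.
METRIC_SCALES = {
    "MK": 0.95, "AK": 0.80, "RK": 1.30, "KFA": 0.35,
    "MD": 0.90, "FA": 0.40, "Ad": 1.20, "RD": 0.70,
    "FN": 30.0, "length": 40.0,
}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 21
    n_controls: int = 19
    n_regions: int = 90
    metrics: tuple[str, ...] = GM_METRICS
    seed: int = 0
    gm_effect: float = 0.5       # fraction of latent edges relocated in patients
    wm_effect: float = 0.3       # patient edge-weight attenuation / rewiring fraction
    noise_sd: float = 0.1        # log-scale observation noise
    cognition_link: float = 4.5  # slope tying MMSE/MoCA to the integrity factor
    ws_k: int = 6                # lattice neighbors of the GM latent network
    ws_p: float = 0.1            # shortcut rewiring probability
    wm_ws_k: int = 14            # lattice neighbors of the WM latent network
                                 # (tractography networks are denser than the
                                 # GM covariance skeleton)
    corr_edge: float = 0.6       # target correlation on latent edges (r0)
    corr_decay: float = 0.45     # per-graph-distance decay (rho)
    parity_base: float = 0.65    # patient parity structure: offset-1 strength
    parity_decay: float = 0.85   # decay per odd-offset rank
    parity_even: float = 0.02    # residual strength at even ring offsets
    psd_floor: float = 0.05      # minimum eigenvalue after PSD shrinkage
    false_edge_rate: float = 0.005
    metric_scales: dict = field(default_factory=lambda: dict(METRIC_SCALES))

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "n_regions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gm_effect", "wm_effect", "ws_p", "false_edge_rate",
                     "corr_edge", "corr_decay"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.ws_k < 2 or self.ws_k >= self.n_regions:
            raise ValueError("ws_k must satisfy 2 <= ws_k < n_regions")

    def subject_ids(self) -> tuple[list[str], list[str]]:
        pats = [f"AD{i + 1:02d}" for i in range(self.n_patients)]
        ctls = [f"NC{i + 1:02d}" for i in range(self.n_controls)]
        return pats, ctls

    def region_labels(self) -> list[str]:
        return [f"R{i + 1:03d}" for i in range(self.n_regions)]


@dataclass
class GroundTruth:
    """What the generator injected, for downstream recovery checks."""

    gm_adjacency: dict[str, np.ndarray]       # group -> binary latent matrix
    wm_adjacency: dict[str, np.ndarray]
    target_correlation: dict[str, np.ndarray]  # group -> GM target (log scale)
    effect_sizes: dict[str, float]
    integrity: dict[str, float]               # subject id -> latent factor


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _ws_adjacency(config: CohortConfig, k: int, stream: int) -> np.ndarray:
    g = nx.watts_strogatz_graph(
        config.n_regions, k, config.ws_p,
        seed=int(_rng(config, stream).integers(2**31 - 1)),
    )
    a = np.zeros((config.n_regions, config.n_regions))
    for i, j in g.edges():
        a[i, j] = a[j, i] = 1.0
    return a


def latent_control_adjacency(config: CohortConfig) -> np.ndarray:
    """GM latent small-world network (Watts-Strogatz, ws_k neighbors)."""
    return _ws_adjacency(config, config.ws_k, _S_LATENT)


def wm_latent_adjacency(config: CohortConfig) -> np.ndarray:
    """WM latent network; denser than the GM skeleton (wm_ws_k neighbors)."""
    return _ws_adjacency(config, config.wm_ws_k, _S_WM_LATENT)


def _ring_distance(n: int) -> np.ndarray:
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, n - d)


def perturb_adjacency(
    adj: np.ndarray, effect: float, config: CohortConfig, stream: int
) -> np.ndarray:
    """Relocate an ``effect`` fraction of edges to mid-range ring pairs.

    Per-edge uniforms and replacement proposals are drawn from edge-indexed
    streams, so the relocated sets are nested across effect values.
    """
    n = adj.shape[0]
    out = adj.copy()
    iu, ju = np.nonzero(np.triu(adj, 1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    u = np.random.default_rng([config.seed, stream]).uniform(size=len(edges))
    for idx, (i, j) in enumerate(edges):
        if u[idx] >= effect:
            continue
        erng = np.random.default_rng([config.seed, stream, idx])
        for _ in range(200):
            a = int(erng.integers(n))
            b = (a + int(erng.integers(4, 13))) % n
            if a == b or out[a, b] != 0:
                continue
            out[i, j] = out[j, i] = 0.0
            out[a, b] = out[b, a] = 1.0
            break
    return out


def _nearest_correlation_repair(c: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Eigenvalue-floor a symmetric matrix and rescale to unit diagonal."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    if w.min() > floor:
        return c
    warnings.warn(
        "target covariance not positive definite; repaired by eigenvalue flooring",
        stacklevel=2,
    )
    w = np.maximum(w, floor)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def _pair_jitter(config: CohortConfig) -> np.ndarray:
    """Symmetric per-pair multiplicative jitter, shared between groups."""
    rng = _rng(config, _S_JITTER)
    j = rng.uniform(0.85, 1.0, size=(config.n_regions, config.n_regions))
    j = np.triu(j, 1)
    return j + j.T


def shrink_to_psd(c_off: np.ndarray, floor: float = 0.05) -> tuple[np.ndarray, float]:
    """Scale an off-diagonal block so t*C_off + I has min eigenvalue >= floor.

    Unlike eigenvalue flooring this preserves the ranking of every entry —
    the thresholded topology of the target is exactly the designed one.
    Returns (correlation matrix, shrink factor t).
    """
    w = np.linalg.eigvalsh((c_off + c_off.T) / 2.0)
    t = 1.0
    if w.min() < floor - 1.0:
        t = (1.0 - floor) / (-w.min())
    c = t * c_off + np.eye(c_off.shape[0])
    return c, t


def structure_target_raw(adj: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Graph-distance-decay correlation structure (off-diagonal, jittered).

    r(i, j) = corr_edge * corr_decay^(d(i,j) - 1) * jitter(i, j), with d the
    shortest-path distance in the latent graph (0 for unreachable pairs).
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    d = shortest_path(csr_matrix(adj.astype(np.int8)), method="D",
                      directed=False, unweighted=True)
    with np.errstate(over="ignore"):
        c = np.where(np.isfinite(d) & (d > 0),
                     config.corr_edge * config.corr_decay ** (d - 1.0), 0.0)
    return c * _pair_jitter(config)


def parity_target_raw(config: CohortConfig) -> np.ndarray:
    """Triangle-suppressed correlation structure (off-diagonal, jittered).

    Strong correlations sit on odd ring offsets only, decaying with offset
    rank; even offsets carry a residual.  Because odd +/- odd is even, the
    top-K graph of this structure contains no triangles at any K covered by
    the odd offsets, and its slow spatial reach keeps path lengths large.
    """
    n = config.n_regions
    ring = _ring_distance(n)
    g = np.where(ring % 2 == 1,
                 config.parity_base * config.parity_decay ** ((ring - 1) // 2),
                 config.parity_even)
    np.fill_diagonal(g, 0.0)
    return g * _pair_jitter(config)


def gm_targets(config: CohortConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(control target, patient target, control latent adjacency).

    The patient target mixes the control structure with the parity structure
    in proportion gm_effect before PSD shrinkage; gm_effect = 0 gives
    byte-identical targets.
    """
    adj = latent_control_adjacency(config)
    cs = structure_target_raw(adj, config)
    c_nc, _ = shrink_to_psd(cs, config.psd_floor)
    if config.gm_effect == 0:
        return c_nc, c_nc.copy(), adj
    cp = parity_target_raw(config)
    c_ad, _ = shrink_to_psd(
        (1.0 - config.gm_effect) * cs + config.gm_effect * cp, config.psd_floor
    )
    return c_nc, c_ad, adj


def _sample_log_mvn(
    corr: np.ndarray, n_subjects: int, rng: np.random.Generator, noise_sd: float
) -> np.ndarray:
    chol = np.linalg.cholesky(_nearest_correlation_repair(corr))
    z = rng.standard_normal((n_subjects, corr.shape[0])) @ chol.T
    if noise_sd > 0:
        eps = rng.standard_normal(z.shape)
        z = (z + noise_sd * eps) / np.sqrt(1.0 + noise_sd**2)
    return z


def generate_gm_cohort(
    config: CohortConfig,
) -> tuple[dict[str, tuple[RegionalMetricTable, RegionalMetricTable]], GroundTruth]:
    """Regional metric tables for both groups, one pair per metric.

    Returns ``{metric: (patients_table, controls_table)}`` plus the ground
    truth.  Values are strictly positive (log-normal observation model).
    """
    c_nc, c_ad, adj_nc = gm_targets(config)
    # a binary "patient network" for ground-truth bookkeeping: the target's
    # own topology at the density of the control latent graph
    from .construct import ConnectivityMatrix as _CM, threshold_by_sparsity as _th

    n_latent_edges = int(adj_nc.sum() // 2)
    _cm = _CM(labels=config.region_labels(),
              values=c_ad * (1 - np.eye(config.n_regions)),
              weight_kind="correlation")
    adj_ad = _th(_cm, n_latent_edges / (config.n_regions * (config.n_regions - 1) / 2),
                 mode="binary").adjacency
    pats, ctls = config.subject_ids()
    regions = config.region_labels()
    gm_metrics = [m for m in config.metrics if m in GM_METRICS]
    tables: dict[str, tuple[RegionalMetricTable, RegionalMetricTable]] = {}
    for m_idx, metric in enumerate(gm_metrics):
        rng = np.random.default_rng([config.seed, _S_GM_SAMPLE, m_idx])
        scale = config.metric_scales.get(metric, 1.0)
        mu, s = np.log(scale), 0.1
        z_ad = _sample_log_mvn(c_ad, config.n_patients, rng, config.noise_sd)
        z_nc = _sample_log_mvn(c_nc, config.n_controls, rng, config.noise_sd)
        tables[metric] = (
            RegionalMetricTable(
                subject_ids=pats, groups=["patient"] * config.n_patients,
                regions=regions, values=np.exp(mu + s * z_ad), metric=metric,
            ),
            RegionalMetricTable(
                subject_ids=ctls, groups=["control"] * config.n_controls,
                regions=regions, values=np.exp(mu + s * z_nc), metric=metric,
            ),
        )
    truth = GroundTruth(
        gm_adjacency={"patient": adj_ad, "control": adj_nc},
        wm_adjacency={},
        target_correlation={"patient": c_ad, "control": c_nc},
        effect_sizes={"gm_effect": config.gm_effect, "wm_effect": config.wm_effect},
        integrity=integrity_factors(config),
    )
    return tables, truth


def integrity_factors(config: CohortConfig) -> dict[str, float]:
    """Per-subject network-integrity latent factor (patients shifted down)."""
    rng = _rng(config, _S_INTEGRITY)
    pats, ctls = config.subject_ids()
    t_ad = -2.0 + 0.8 * rng.standard_normal(len(pats))
    t_nc = 0.0 + 0.4 * rng.standard_normal(len(ctls))
    out = dict(zip(pats, t_ad.tolist()))
    out.update(zip(ctls, t_nc.tolist()))
    return out


def generate_wm_cohort(
    config: CohortConfig,
) -> tuple[dict[str, dict[str, ConnectivityMatrix]], GroundTruth]:
    """Per-subject weighted connectivity matrices for every edge metric.

    Returns ``{subject_id: {metric: ConnectivityMatrix}}`` plus ground truth.
    Streamline-count (FN) matrices are nonnegative integers, nonzero exactly
    on the group's latent edges plus a small false-edge rate; per-edge metric
    weights are positive reals on existing edges, attenuated by ``wm_effect``
    in patients and modulated by the subject's integrity factor.
    """
    adj_nc = wm_latent_adjacency(config)
    adj_ad = perturb_adjacency(adj_nc, config.wm_effect, config, _S_WM_PERTURB)
    n = config.n_regions
    regions = config.region_labels()
    integrity = integrity_factors(config)
    pats, ctls = config.subject_ids()
    jitter_rng = _rng(config, _S_WM_JITTER)
    ejit = np.exp(0.15 * jitter_rng.standard_normal((n, n)))
    ejit = np.triu(ejit, 1) + np.triu(ejit, 1).T  # shared per-edge jitter
    wm_metrics = [m for m in config.metrics if m != "FN" and m in WM_METRICS]

    subjects: dict[str, dict[str, ConnectivityMatrix]] = {}
    for s_idx, (sid, group) in enumerate(
        [(p, "patient") for p in pats] + [(c, "control") for c in ctls]
    ):
        rng = np.random.default_rng([config.seed, _S_WM_SAMPLE, s_idx])
        latent = adj_ad if group == "patient" else adj_nc
        iu, ju = np.triu_indices(n, 1)
        on = latent[iu, ju] > 0
        fn = np.zeros((n, n))
        fn_vals = 1 + rng.negative_binomial(3, 3 / 32.0, size=int(on.sum()))
        fn[iu[on], ju[on]] = fn_vals
        false = (~on) & (rng.uniform(size=iu.size) < config.false_edge_rate)
        fn[iu[false], ju[false]] = rng.integers(1, 3, size=int(false.sum()))
        fn = fn + fn.T
        mask = fn > 0
        atten = (1.0 - config.wm_effect) if group == "patient" else 1.0
        # integrity drives weights; an extra nuisance scale keeps the
        # cognition association realistic rather than near-deterministic
        subj_scale = atten * np.exp(0.1 * integrity[sid]
                                    + 0.08 * rng.standard_normal())
        mats = {
            "FN": ConnectivityMatrix(
                labels=regions, values=fn, weight_kind="FN", level="subject"
            )
        }
        for metric in wm_metrics:
            scale = config.metric_scales.get(metric, 1.0)
            noise = np.exp(config.noise_sd * rng.standard_normal((n, n)))
            noise = np.triu(noise, 1) + np.triu(noise, 1).T
            vals = np.where(mask, scale * ejit * noise * subj_scale, 0.0)
            np.fill_diagonal(vals, 0.0)
            mats[metric] = ConnectivityMatrix(
                labels=regions, values=vals, weight_kind=metric, level="subject"
            )
        subjects[sid] = mats
    truth = GroundTruth(
        gm_adjacency={},
        wm_adjacency={"patient": adj_ad, "control": adj_nc},
        target_correlation={},
        effect_sizes={"gm_effect": config.gm_effect, "wm_effect": config.wm_effect},
        integrity=integrity,
    )
    return subjects, truth


def generate_covariates(config: CohortConfig):
    """Demographics and cognition: subject id, group, age, sex, MMSE, MoCA.

    MMSE/MoCA are monotone functions of the integrity factor plus noise,
    clipped to [0, 30]; ``cognition_link=0`` decouples them from integrity.
    Sex counts follow the 12F/9M vs 9F/10M proportions of the emulated
    cohort; ages are drawn near 74 (patients) and 70 (controls).
    """
    import pandas as pd

    rng = _rng(config, _S_COVARIATES)
    integrity = integrity_factors(config)
    pats, ctls = config.subject_ids()
    rows = []
    for sid, group in [(p, "patient") for p in pats] + [(c, "control") for c in ctls]:
        if group == "patient":
            age = float(np.clip(73.57 + 6.87 * rng.standard_normal(), 55, 92))
        else:
            age = float(np.clip(70.0 + 8.08 * rng.standard_normal(), 55, 92))
        t = integrity[sid]
        mmse = float(np.clip(28.2 + config.cognition_link * t
                             + 1.2 * rng.standard_normal(), 0, 30))
        moca = float(np.clip(27.9 + 1.45 * config.cognition_link * t
                             + 1.5 * rng.standard_normal(), 0, 30))
        rows.append({"subject_id": sid, "group": group, "age": round(age, 2),
                     "sex": "", "MMSE": round(mmse, 2), "MoCA": round(moca, 2)})
    df = pd.DataFrame(rows)
    for group, n_f in (("patient", round(12 / 21 * config.n_patients)),
                       ("control", round(9 / 19 * config.n_controls))):
        idx = df.index[df["group"] == group].to_numpy()
        fem = rng.permutation(idx)[:n_f]
        df.loc[idx, "sex"] = "M"
        df.loc[fem, "sex"] = "F"
    return df
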