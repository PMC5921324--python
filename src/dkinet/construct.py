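"""Network construction: structural-covariance matrices and sparsity thresholding.

Grey-matter networks are built at the group level by correlating one regional
diffusion metric (e.g. mean kurtosis) across subjects for every pair of
regions.  White-matter networks are per-subject weighted matrices whose edge
weights are streamline counts (FN), mean fiber length, or mean per-edge
diffusion metrics.  Either kind of matrix is turned into a graph by keeping
the top-K entries at a given sparsity (fraction of the N(N-1)/2 possible
edges).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: weight kinds a ConnectivityMatrix may carry
WEIGHT_KINDS = (
    "correlation", "FN", "length",
    "FA", "MD", "Ad", "RD", "MK", "AK", "RK", "KFA",
)


@dataclass
class RegionalMetricTable:
    """Subjects x regions values of one regional diffusion metric.

    ``values[s, r]`` is the metric (voxel average over region ``r``) for
    subject ``s``; every value must be finite and the metric is assumed
    strictly positive (kurtosis and diffusivity are positive quantities).
    """

    subject_ids: list[str]
    groups: list[str]
    regions: list[str]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_sub, n_reg = self.values.shape
        if len(self.subject_ids) != n_sub or len(self.groups) != n_sub:
            raise ValueError("subject_ids/groups length does not match rows")
        if len(self.regions) != n_reg:
            raise ValueError("region labels do not match number of columns")
        if len(set(self.regions)) != n_reg:
            dupes = sorted({r for r in self.regions if self.regions.count(r) > 1})
            raise ValueError(f"duplicate region labels: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in regional metric table")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.regions)
        df.insert(0, "group", self.groups)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region weighted matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    weight_kind: str = "correlation"
    level: str = "group"  # group | subject

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if self.weight_kind not in WEIGHT_KINDS:
            raise ValueError(f"unknown weight_kind {self.weight_kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("connectivity matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("connectivity matrix diagonal must be zero")
        if self.weight_kind == "correlation" and np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.labels)


@dataclass
class ThresholdedGraph:
    """Undirected simple graph at one sparsity level.

    ``adjacency`` holds edge weights (1.0 everywhere in binary mode); it is
    symmetric with a zero diagonal and exactly ``floor(sparsity*N(N-1)/2)``
    nonzero upper-triangular entries.
    """

    labels: list[str]
    adjacency: np.ndarray
    sparsity: float
    mode: str = "binary"  # binary | weighted
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    def degrees(self) -> np.ndarray:
        return (self.adjacency > 0).sum(axis=1)

    def to_networkx(self):
        """networkx view; weighted graphs carry 'weight' and 'dist' = 1/weight."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        iu, ju = np.nonzero(np.triu(self.adjacency, 1))
        for i, j in zip(iu.tolist(), ju.tolist()):
            w = float(self.adjacency[i, j])
            g.add_edge(i, j, weight=w, dist=1.0 / w)
        return g


def gm_correlation_matrix(table: RegionalMetricTable) -> ConnectivityMatrix:
    """Across-subject Pearson correlation of regional values for every pair.

    Entry (i, j) is the Pearson correlation, across subjects, of region i's
    and region j's metric values; the diagonal is forced to zero.  A constant
    region column has undefined correlations: they are set to 0 and a warning
    names the region.
    """
    if table.n_subjects < 3:
        raise ValueError("need at least 3 subjects for a correlation network")
    if table.n_regions < 2:
        raise ValueError("need at least 2 regions")
    x = table.values
    sd = x.std(axis=0)
    constant = np.where(sd == 0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    if constant.size:
        names = [table.regions[i] for i in constant]
        warnings.warn(
            f"constant region column(s) {names}: correlations set to 0",
            stacklevel=2,
        )
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        labels=list(table.regions), values=r, weight_kind="correlation", level="group"
    )


def wm_edge_matrices(
    fn: ConnectivityMatrix,
    per_edge_metrics: dict[str, ConnectivityMatrix],
    fn_min: int = 1,
) -> dict[str, ConnectivityMatrix]:
    """Mask per-edge metric matrices to the edges supported by the FN matrix.

    An edge exists where the streamline count is >= ``fn_min``; every metric
    layer (and FN itself) is masked to that common edge set, so all outputs
    share one topology and differ only in weights.
    """
    labels = fn.labels
    for name, m in per_edge_metrics.items():
        if m.labels != labels:
            bad = sorted(set(m.labels) ^ set(labels))
            raise ValueError(f"label mismatch for metric {name!r}: {bad}")
    mask = fn.values >= fn_min
    np.fill_diagonal(mask, False)
    out: dict[str, ConnectivityMatrix] = {
        "FN": ConnectivityMatrix(
            labels=list(labels),
            values=np.where(mask, fn.values, 0.0),
            weight_kind="FN",
            level=fn.level,
        )
    }
    for name, m in per_edge_metrics.items():
        out[name] = ConnectivityMatrix(
            labels=list(labels),
            values=np.where(mask, m.values, 0.0),
            weight_kind=m.weight_kind,
            level=m.level,
        )
    return out


def _ranking_values(matrix: ConnectivityMatrix, rank: str) -> np.ndarray:
    if matrix.weight_kind == "correlation":
        if rank == "abs":
            return np.abs(matrix.values)
        if rank == "positive":
            return np.where(matrix.values > 0, matrix.values, -np.inf)
        raise ValueError(f"unknown ranking rule {rank!r}")
    return matrix.values


def max_edges(n: int) -> int:
    return n * (n - 1) // 2


def edge_count_at_sparsity(sparsity: float, n: int) -> int:
    """floor(sparsity * N(N-1)/2), guarded against float round-off."""
    return int(np.floor(sparsity * max_edges(n) + 1e-9))


def threshold_by_sparsity(
    matrix: ConnectivityMatrix,
    sparsity: float,
    mode: str = "binary",
    rank: str = "abs",
) -> ThresholdedGraph:
    """Keep the K = floor(sparsity*N(N-1)/2) strongest edges.

    Correlation matrices are ranked by |r| by default (``rank='abs'``;
    ``rank='positive'`` restricts to positive entries); other matrices by raw
    weight.  Ties at the cutoff are broken by lexicographic (i, j) node-index
    order so edge sets are reproducible, and the sweep over increasing
    sparsity is nested by construction.  Weighted graphs carry the magnitude
    of the original weight.
    """
    if not (0.0 < sparsity <= 1.0):
        raise ValueError("sparsity must lie in (0, 1]")
    if mode not in ("binary", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    n = matrix.n_regions
    k = edge_count_at_sparsity(sparsity, n)
    if k == 0:
        raise ValueError(f"sparsity too low for N: {sparsity} keeps 0 of {max_edges(n)} edges")
    rv = _ranking_values(matrix, rank)
    iu, ju = np.triu_indices(n, 1)
    vals = rv[iu, ju]
    # primary key: descending ranking value; ties: lexicographic (i, j)
    order = np.lexsort((ju, iu, -vals))[:k]
    sel_i, sel_j = iu[order], ju[order]
    if not np.all(np.isfinite(vals[order])):
        raise ValueError("not enough rankable edges at this sparsity")
    adj = np.zeros((n, n))
    if mode == "binary":
        adj[sel_i, sel_j] = 1.0
    else:
        w = np.abs(matrix.values[sel_i, sel_j])
        if np.any(w <= 0):
            raise ValueError("weighted mode requires nonzero weights on kept edges")
        adj[sel_i, sel_j] = w
    adj = adj + adj.T
    return ThresholdedGraph(
        labels=list(matrix.labels),
        adjacency=adj,
        sparsity=float(sparsity),
        mode=mode,
        meta={"weight_kind": matrix.weight_kind, "rank": rank},
    )


def sparsity_grid(lo: float = 0.06, hi: float = 0.40, step: float = 0.01) -> np.ndarray:
    """Inclusive sparsity grid; default 6%..40% in 1% steps (35 points)."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    n = int(round((hi - lo) / step)) + 1 if step > 0 else 1
    grid = lo + step * np.arange(n)
    return grid[grid <= hi + 1e-12]


def sparsity_sweep(
    matrix: ConnectivityMatrix,
    lo: float = 0.06,
    hi: float = 0.40,
    step: float = 0.01,
    mode: str = "binary",
    rank: str = "abs",
) -> list[ThresholdedGraph]:
    """One thresholded graph per grid point, nested along the sweep."""
    return [
        threshold_by_sparsity(matrix, float(s), mode=mode, rank=rank)
        for s in sparsity_grid(lo, hi, step)
    ]
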