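"""Hub identification from normalized betweenness centrality.

A region is a hub when its betweenness exceeds 1.5 times the network
average, i.e. normalized betweenness bi = Bi / B > 1.5 (strict inequality).
Cortex classes (primary / association / paralimbic) are carried as metadata
only; no automatic anatomical classification is attempted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .construct import ThresholdedGraph

#: pandas frame with columns region, cortex_class, Bi, bi, is_hub,
#: sorted by bi descending (ties by region label)
HubTable = pd.DataFrame

HUB_THRESHOLD = 1.5


def normalize_betweenness(bi_raw: np.ndarray) -> np.ndarray:
    """bi = Bi / B with B the network-average betweenness.

    If every node has zero betweenness (B = 0) all bi are defined as 0 with
    a warning; negative input is a contract violation upstream.
    """
    bi_raw = np.asarray(bi_raw, dtype=float)
    if bi_raw.size == 0:
        raise ValueError("need at least one node")
    if np.any(bi_raw < 0):
        raise ValueError("betweenness values must be nonnegative")
    b = bi_raw.mean()
    if b == 0:
        warnings.warn("network-average betweenness is 0; all bi set to 0",
                      stacklevel=2)
        return np.zeros_like(bi_raw)
    return bi_raw / b


def identify_hubs(
    bi: np.ndarray,
    labels: list[str],
    classes: list[str] | None = None,
    threshold: float = HUB_THRESHOLD,
    bi_raw: np.ndarray | None = None,
) -> HubTable:
    """Hub table sorted by normalized betweenness, descending.

    ``is_hub`` is True where bi strictly exceeds ``threshold`` (bi == 1.5 is
    not a hub).  Ties in bi are ordered by region label.
    """
    bi = np.asarray(bi, dtype=float)
    if len(labels) != bi.size:
        raise ValueError("labels do not align with bi values")
    if classes is not None and len(classes) != bi.size:
        raise ValueError("classes do not align with bi values")
    df = pd.DataFrame({
        "region": labels,
        "cortex_class": classes if classes is not None else [""] * bi.size,
        "Bi": bi_raw if bi_raw is not None else np.full(bi.size, np.nan),
        "bi": bi,
        "is_hub": bi > threshold,
    })
    df = df.sort_values(["bi", "region"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df


def hub_table_from_graph(
    graph: ThresholdedGraph,
    classes: list[str] | None = None,
    threshold: float = HUB_THRESHOLD,
) -> HubTable:
    """Betweenness -> normalization -> hub flags for one thresholded graph."""
    from .metrics import betweenness

    bi_raw, _ = betweenness(graph)
    bi = normalize_betweenness(bi_raw)
    return identify_hubs(bi, graph.labels, classes=classes,
                         threshold=threshold, bi_raw=bi_raw)


def export_brainnet(
    node_path,
    edge_path,
    hub_table: HubTable,
    adjacency: np.ndarray,
    labels: list[str],
    coords: np.ndarray | None = None,
) -> None:
    """Write BrainNet-Viewer ``.node`` / ``.edge`` files.

    ``labels`` gives the node order of ``adjacency`` (the hub table itself is
    bi-sorted).  The ``.node`` format is six whitespace columns per region:
    x, y, z, color code (hub flag), size (bi), label.  If no MNI coordinates
    are supplied, synthetic ring-layout coordinates are written (sufficient
    for format round-trips; they are not anatomical positions).
    """
    n = len(labels)
    if adjacency.shape != (n, n):
        raise ValueError("adjacency does not match label count")
    by_region = hub_table.set_index("region")
    if coords is None:
        theta = 2 * np.pi * np.arange(n) / n
        coords = np.column_stack(
            [60 * np.cos(theta), 60 * np.sin(theta), np.zeros(n)]
        )
    with open(node_path, "w") as fh:
        for i, lab in enumerate(labels):
            row = by_region.loc[lab]
            safe_label = str(lab).replace(" ", "_")
            fh.write(
                f"{coords[i, 0]:.2f}\t{coords[i, 1]:.2f}\t{coords[i, 2]:.2f}\t"
                f"{int(row.is_hub)}\t{row.bi:.4f}\t{safe_label}\n"
            )
    np.savetxt(edge_path, adjacency, fmt="%.6g", delimiter="\t")
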