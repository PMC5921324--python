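"""Readers/writers for the plain-text formats the pipeline exchanges.

Regional metric tables and covariates travel as TSV; connectivity matrices
as N x N whitespace-delimited square text with a sidecar label file (one
region label per line); run configuration as YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .construct import ConnectivityMatrix, RegionalMetricTable


def write_regional_table(table: RegionalMetricTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_regional_table(path, metric: str = "") -> RegionalMetricTable:
    """Read a TSV with subject_id, group, then one column per region."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    raw_regions = [c for c in header if c not in ("subject_id", "group")]
    if len(set(raw_regions)) != len(raw_regions):
        dupes = sorted({r for r in raw_regions if raw_regions.count(r) > 1})
        raise ValueError(f"{path}: duplicate region columns {dupes}")
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str})
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    regions = [c for c in df.columns if c not in ("subject_id", "group")]
    vals = df[regions]
    bad = vals.map(lambda v: not isinstance(v, (int, float, np.number))
                   or pd.isna(v))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value at row {r + 2}, column {regions[c]!r}"
        )
    return RegionalMetricTable(
        subject_ids=df["subject_id"].tolist(),
        groups=df["group"].tolist(),
        regions=regions,
        values=vals.to_numpy(dtype=float),
        metric=metric,
    )


def write_matrix(matrix: ConnectivityMatrix, path, labels_path=None) -> None:
    np.savetxt(path, matrix.values, fmt="%.10g")
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(matrix.labels) + "\n")


def read_matrix(
    path,
    labels_path=None,
    weight_kind: str = "correlation",
    level: str = "group",
    atol: float = 1e-8,
) -> ConnectivityMatrix:
    """Read an N x N square text matrix (plus optional sidecar labels).

    Asymmetry within ``atol`` is silently symmetrized; larger asymmetry is
    symmetrized by averaging with a warning.  The diagonal is zeroed.
    """
    vals = np.loadtxt(path, ndmin=2)
    if vals.shape[0] != vals.shape[1]:
        raise ValueError(f"{path}: matrix is not square {vals.shape}")
    asym = np.abs(vals - vals.T).max()
    if asym > atol:
        warnings.warn(
            f"{path}: asymmetry {asym:.3g} exceeds {atol:.0e}; "
            "symmetrized by averaging", stacklevel=2,
        )
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    if labels_path is not None:
        labels = Path(labels_path).read_text().split()
    else:
        labels = [f"R{i + 1:03d}" for i in range(vals.shape[0])]
    if len(labels) != vals.shape[0]:
        raise ValueError(f"{labels_path}: {len(labels)} labels for "
                         f"{vals.shape[0]} rows")
    return ConnectivityMatrix(labels=labels, values=vals,
                              weight_kind=weight_kind, level=level)


REGION_METADATA_COLUMNS = ("label", "abbreviation", "x", "y", "z",
                           "cortex_class")
CORTEX_CLASSES = {"primary", "association", "paralimbic"}


def read_region_metadata(path) -> pd.DataFrame:
    """Region metadata TSV: label, abbreviation, MNI x/y/z, cortex class.

    Coordinates feed BrainNet ``.node`` export; cortex classes annotate hub
    tables.  Classes must be primary / association / paralimbic
    (case-insensitive).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REGION_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if df["label"].duplicated().any():
        dupes = df.loc[df["label"].duplicated(), "label"].tolist()
        raise ValueError(f"{path}: duplicate region labels {dupes}")
    df["cortex_class"] = df["cortex_class"].str.lower()
    bad = sorted(set(df["cortex_class"]) - CORTEX_CLASSES)
    if bad:
        raise ValueError(f"{path}: unknown cortex classes {bad}")
    for c in ("x", "y", "z"):
        df[c] = df[c].astype(float)
    return df[list(REGION_METADATA_COLUMNS)]


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs.

    ``cohort`` holds synthetic-cohort settings (see CohortConfig); set
    ``input_dir`` instead to load previously written tables.  The config
    copy is serialized into the run's output directory.
    """

    out_dir: str = "dkinet-run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)   # CohortConfig overrides
    input_dir: str | None = None
    sparsity_lo: float = 0.06
    sparsity_hi: float = 0.40
    sparsity_step: float = 0.01
    gm_mode: str = "binary"         # small-world curve graphs
    gm_perm_mode: str = "weighted"  # permutation-test graphs
    rank: str = "abs"               # correlation edge ranking: abs | positive
    wm_mode: str = "weighted"
    wm_sparsity: float = 0.15       # per-subject WM attribute threshold
    hub_sparsity: float = 0.15
    n_rand: int = 100
    n_perm: int = 1000
    fn_min: int = 1
    correction: str = "fdr_bh"
    gm_metric: str = "MK"           # metric driving permutation + hub stages
    wm_metrics: tuple = ("FN", "length", "MK", "KFA", "AK", "RK",
                         "MD", "FA", "Ad", "RD")

    def __post_init__(self) -> None:
        # normalize to the JSON/YAML-serializable form so round trips compare equal
        self.cohort = {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.cohort.items()}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wm_metrics"] = list(d["wm_metrics"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "wm_metrics" in d:
            d["wm_metrics"] = tuple(d["wm_metrics"])
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
        return cls.from_dict(data)
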