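"""End-to-end reproducible analysis run.

Stages: synthetic cohort (or loaded tables) -> group-level grey-matter
correlation matrices -> sparsity-swept small-world curves -> per-subject
white-matter attributes with ANCOVA -> hub tables (+ BrainNet export) ->
permutation curves for the grey-matter group comparison -> partial
correlations with cognition -> JSON manifest with checksums.

Every stage derives its seed deterministically from the run seed, so two
runs with the same config produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_covariates, generate_gm_cohort, generate_wm_cohort
from .construct import gm_correlation_matrix, sparsity_grid, threshold_by_sparsity
from .hubs import export_brainnet, hub_table_from_graph
from .io import RunConfig, read_regional_table, write_matrix, write_regional_table
from .metrics import characteristic_path_length, clustering_coefficient, efficiency, small_worldness
from .stats import (
    adjust_pvalues,
    ancova_group_effect,
    demographics_compare,
    gm_permutation_test,
    partial_correlation,
)

logger = logging.getLogger(__name__)

# per-stage seed offsets below 2**31
_SEED_CURVES, _SEED_WM, _SEED_PERM = 101, 202, 303


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def subject_wm_attributes(
    subjects: dict,
    metrics: tuple,
    sparsity: float,
    mode: str,
    n_rand: int,
    seed: int,
) -> pd.DataFrame:
    """Per-subject network attributes (Lp, Cp, lambda, gamma, sigma, Eloc, Eg)
    for each edge-metric layer, thresholded at one sparsity."""
    rows = []
    for s_idx, (sid, mats) in enumerate(sorted(subjects.items())):
        for m_idx, metric in enumerate(metrics):
            if metric not in mats:
                continue
            g = threshold_by_sparsity(mats[metric], sparsity, mode=mode)
            sw = small_worldness(
                g, n_rand=n_rand, seed=seed + 1000 * s_idx + m_idx
            )
            eg, eloc = efficiency(g)
            rows.append({
                "subject_id": sid, "metric": metric,
                "Lp": sw.lp, "Cp": sw.cp, "lambda": sw.lam,
                "gamma": sw.gamma, "sigma": sw.sigma,
                "Eloc": eloc, "Eg": eg,
            })
    return pd.DataFrame(rows)


WM_ATTRIBUTES = ("Lp", "Cp", "lambda", "gamma", "sigma", "Eloc", "Eg")


def wm_group_comparison(
    attrs: pd.DataFrame, covariates: pd.DataFrame, correction: str = "fdr_bh"
) -> pd.DataFrame:
    """Table-2-style comparison: per metric x attribute group mean (SD),
    ANCOVA F/p with age+sex covariates, multiplicity-adjusted within each
    attribute across metrics."""
    cov = covariates.set_index("subject_id")
    df = attrs.join(cov, on="subject_id")
    rows = []
    for attribute in WM_ATTRIBUTES:
        for metric in df["metric"].unique():
            sub = df[df["metric"] == metric].dropna(subset=[attribute])
            res = ancova_group_effect(
                sub[attribute].to_numpy(), sub["group"].to_numpy(),
                age=sub["age"].to_numpy(), sex=sub["sex"].to_numpy(),
                metric=metric, attribute=attribute,
            )
            by_g = sub.groupby("group")[attribute]
            summary = {
                f"{g}_mean_sd": f"{v.mean():.3g}({v.std(ddof=1):.2g})"
                for g, v in by_g
            }
            rows.append({"attribute": attribute, "metric": metric, **summary,
                         "F": res.f_statistic, "p": res.p})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for attribute in WM_ATTRIBUTES:
        m = out["attribute"] == attribute
        out.loc[m, "p_adj"] = adjust_pvalues(out.loc[m, "p"], correction)
    return out


def cognition_partial_correlations(
    attrs: pd.DataFrame,
    covariates: pd.DataFrame,
    group: str = "patient",
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Partial correlations (age and sex as confounders) between each
    metric x attribute and the MMSE/MoCA scores, within one group."""
    cov = covariates.set_index("subject_id")
    df = attrs.join(cov, on="subject_id")
    df = df[df["group"] == group]
    sex_num = (df["sex"] == "F").astype(float)
    rows = []
    for score in ("MMSE", "MoCA"):
        for attribute in WM_ATTRIBUTES:
            for metric in df["metric"].unique():
                sub = df[df["metric"] == metric]
                ok = sub[attribute].notna()
                z = np.column_stack([sub["age"][ok], sex_num[sub.index][ok]])
                res = partial_correlation(
                    sub[attribute][ok].to_numpy(), sub[score][ok].to_numpy(),
                    covariates=z, attribute=f"{metric}:{attribute}", score=score,
                )
                rows.append({"score": score, "attribute": attribute,
                             "metric": metric, "r": res.r, "p": res.p,
                             "evaluable": res.evaluable, "n": res.n})
    out = pd.DataFrame(rows)
    ok = out["evaluable"] & out["p"].notna()
    out["p_adj"] = np.nan
    out.loc[ok, "p_adj"] = adjust_pvalues(out.loc[ok, "p"], correction)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    manifest: dict = {
        "dkinet_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": {},
        "warnings": [],
        "timings_s": {},
    }
    caught: list[str] = []

    def record(kind: str, *paths: Path) -> None:
        manifest["artifacts"].setdefault(kind, {})
        for p in paths:
            manifest["artifacts"][kind][str(p.relative_to(out))] = _sha256(p)

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                try:
                    fn()
                except Exception as err:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
                caught.extend(f"{name}: {w.message}" for w in wlist)
            manifest["timings_s"][name] = round(time.time() - t0, 3)
        return wrap

    # --- cohort -----------------------------------------------------------
    ccfg = CohortConfig(seed=config.seed, **config.cohort)
    state: dict = {}

    @stage("cohort")
    def _cohort():
        cdir = out / "cohort"
        cdir.mkdir(exist_ok=True)
        if config.input_dir:
            indir = Path(config.input_dir)
            tables = {}
            for f in sorted(indir.glob("gm_*_patient.tsv")):
                metric = f.stem.split("_")[1]
                tables[metric] = (
                    read_regional_table(f, metric=metric),
                    read_regional_table(indir / f"gm_{metric}_control.tsv",
                                        metric=metric),
                )
            covariates = pd.read_csv(indir / "covariates.tsv", sep="\t")
            subjects = None
        else:
            tables, _ = generate_gm_cohort(ccfg)
            subjects, _ = generate_wm_cohort(ccfg)
            covariates = generate_covariates(ccfg)
        state["tables"] = tables
        state["subjects"] = subjects
        state["covariates"] = covariates
        paths = []
        for metric, (pat, ctl) in tables.items():
            for tab, gname in ((pat, "patient"), (ctl, "control")):
                p = cdir / f"gm_{metric}_{gname}.tsv"
                write_regional_table(tab, p)
                paths.append(p)
        cpath = cdir / "covariates.tsv"
        covariates.to_csv(cpath, sep="\t", index=False)
        paths.append(cpath)
        record("cohort", *paths)
        demo = demographics_compare(covariates)
        dpath = out / "demographics.tsv"
        demo.to_csv(dpath, sep="\t", index=False)
        record("demographics", dpath)

    # --- GM correlation matrices -----------------------------------------
    @stage("gm_matrices")
    def _gm():
        gdir = out / "gm"
        gdir.mkdir(exist_ok=True)
        mats = {}
        paths = []
        for metric, (pat, ctl) in state["tables"].items():
            for tab, gname in ((pat, "patient"), (ctl, "control")):
                cm = gm_correlation_matrix(tab)
                mats[(metric, gname)] = cm
                p = gdir / f"corr_{metric}_{gname}.txt"
                write_matrix(cm, p)
                paths.append(p)
        lab = gdir / "region_labels.txt"
        lab.write_text("\n".join(next(iter(mats.values())).labels) + "\n")
        paths.append(lab)
        state["gm_mats"] = mats
        record("correlation_matrices", *paths)

    # --- small-world curves ----------------------------------------------
    @stage("smallworld_curves")
    def _curves():
        grid = sparsity_grid(config.sparsity_lo, config.sparsity_hi,
                             config.sparsity_step)
        rows = []
        for gname in ("patient", "control"):
            cm = state["gm_mats"][(config.gm_metric, gname)]
            for k, s in enumerate(grid):
                g = threshold_by_sparsity(cm, float(s), mode=config.gm_mode,
                                          rank=config.rank)
                sw = small_worldness(
                    g, n_rand=config.n_rand,
                    seed=config.seed + _SEED_CURVES + k,
                )
                rows.append({
                    "group": gname, "metric": config.gm_metric,
                    "sparsity": round(float(s), 4), "mode": config.gm_mode,
                    "Cp": sw.cp, "Lp": sw.lp, "Cprand": sw.cp_rand,
                    "Lprand": sw.lp_rand, "gamma": sw.gamma,
                    "lambda": sw.lam, "sigma": sw.sigma,
                    "n_rand": sw.n_rand,
                    "n_unreachable_pairs": sw.meta.get("n_unreachable_pairs", 0),
                })
        df = pd.DataFrame(rows)
        p = out / "smallworld_curves.tsv"
        df.to_csv(p, sep="\t", index=False)
        state["curves"] = df
        record("smallworld_curves", p)

    # --- WM per-subject attributes + ANCOVA ------------------------------
    @stage("wm_comparison")
    def _wm():
        if state["subjects"] is None:
            manifest["warnings"].append(
                "wm_comparison: no subject-level matrices (loaded cohort); skipped"
            )
            # still emit empty artifacts so the bundle is complete
            attrs = pd.DataFrame(columns=["subject_id", "metric", *WM_ATTRIBUTES])
        else:
            attrs = subject_wm_attributes(
                state["subjects"], config.wm_metrics, config.wm_sparsity,
                config.wm_mode, config.n_rand,
                seed=config.seed + _SEED_WM,
            )
        p1 = out / "wm_subject_attributes.tsv"
        attrs.to_csv(p1, sep="\t", index=False)
        state["wm_attrs"] = attrs
        if len(attrs):
            comp = wm_group_comparison(attrs, state["covariates"],
                                       config.correction)
        else:
            comp = pd.DataFrame()
        p2 = out / "wm_group_comparison.tsv"
        comp.to_csv(p2, sep="\t", index=False)
        record("wm_comparison", p1, p2)

    # --- hubs -------------------------------------------------------------
    @stage("hubs")
    def _hubs():
        hdir = out / "hubs"
        hdir.mkdir(exist_ok=True)
        paths = []
        for gname in ("patient", "control"):
            cm = state["gm_mats"][(config.gm_metric, gname)]
            g = threshold_by_sparsity(cm, config.hub_sparsity, mode="binary",
                                      rank=config.rank)
            tab = hub_table_from_graph(g)
            p = hdir / f"hubs_{gname}.tsv"
            tab.to_csv(p, sep="\t", index=False)
            node = hdir / f"{gname}.node"
            edge = hdir / f"{gname}.edge"
            export_brainnet(node, edge, tab, g.adjacency, g.labels)
            paths += [p, node, edge]
        record("hub_tables", *paths)

    # --- permutation test --------------------------------------------------
    @stage("permutation")
    def _perm():
        grid = sparsity_grid(config.sparsity_lo, config.sparsity_hi,
                             config.sparsity_step)
        pat, ctl = state["tables"][config.gm_metric]
        res = gm_permutation_test(
            pat, ctl, grid, n_perm=config.n_perm,
            seed=config.seed + _SEED_PERM,
            mode=config.gm_perm_mode, rank=config.rank,
        )
        rows = []
        for attr, r in res.items():
            for k, s in enumerate(r.sparsities):
                rows.append({
                    "attribute": attr, "sparsity": round(float(s), 4),
                    "mode": config.gm_perm_mode,
                    "patient": r.observed_a[k], "control": r.observed_b[k],
                    "diff": r.observed_diff[k], "p": r.p[k],
                    "n_perm": r.n_perm,
                })
        df = pd.DataFrame(rows)
        p1 = out / "permutation_curves.tsv"
        df.to_csv(p1, sep="\t", index=False)
        ranges = {a: r.significant_ranges for a, r in res.items()}
        p2 = out / "permutation_significant_ranges.json"
        p2.write_text(json.dumps(ranges, indent=2))
        state["perm"] = res
        record("permutation", p1, p2)

    # --- cognition ----------------------------------------------------------
    @stage("cognition")
    def _cog():
        if len(state["wm_attrs"]):
            pc = cognition_partial_correlations(
                state["wm_attrs"], state["covariates"],
                correction=config.correction,
            )
        else:
            pc = pd.DataFrame()
        p = out / "cognition_partial_correlations.tsv"
        pc.to_csv(p, sep="\t", index=False)
        record("cognition_partial_corr", p)

    manifest["warnings"].extend(caught)
    manifest["runtime_s"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
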