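"""Simple curve plots for finished runs (small-world and permutation curves)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_smallworld_curves(curves: pd.DataFrame, out_path) -> None:
    """gamma, lambda and sigma against sparsity, one line per group."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2), sharex=True)
    for ax, col in zip(axes, ("gamma", "lambda", "sigma")):
        for group, sub in curves.groupby("group"):
            ax.plot(sub["sparsity"], sub[col], marker=".", label=group)
        ax.axhline(1.0, color="grey", lw=0.7, ls="--")
        ax.set_xlabel("sparsity")
        ax.set_ylabel(col)
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_permutation_curves(perm: pd.DataFrame, out_path, alpha=0.05) -> None:
    """Group Cp/Lp curves with permutation-significant sparsities marked."""
    attrs = perm["attribute"].unique()
    fig, axes = plt.subplots(1, len(attrs), figsize=(5.5 * len(attrs), 3.2))
    for ax, attr in zip(
        axes if len(attrs) > 1 else [axes], attrs
    ):
        sub = perm[perm["attribute"] == attr]
        ax.plot(sub["sparsity"], sub["patient"], marker=".", label="patient")
        ax.plot(sub["sparsity"], sub["control"], marker=".", label="control")
        sig = sub[sub["p"] < alpha]
        lo = min(sub["patient"].min(), sub["control"].min())
        ax.plot(sig["sparsity"], [lo] * len(sig), "k*", ms=5,
                label=f"p < {alpha}")
        ax.set_xlabel("sparsity")
        ax.set_ylabel(attr)
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_run(run_dir, out_dir=None) -> list[Path]:
    """Render the standard figures for a finished pipeline run."""
    run_dir = Path(run_dir)
    out_dir = Path(out_dir) if out_dir else run_dir
    written = []
    sw = run_dir / "smallworld_curves.tsv"
    if sw.exists():
        p = out_dir / "smallworld_curves.png"
        plot_smallworld_curves(pd.read_csv(sw, sep="\t"), p)
        written.append(p)
    pm = run_dir / "permutation_curves.tsv"
    if pm.exists():
        p = out_dir / "permutation_curves.png"
        plot_permutation_curves(pd.read_csv(pm, sep="\t"), p)
        written.append(p)
    return written
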