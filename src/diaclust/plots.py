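"""Report figures: volcano, consensus heatmap, rank-selection curves,
candidate expression heatmap, PCA scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .diffexp import UP_METASTASIS, UP_PRIMARY
from .matrix import IntensityMatrix, SampleSheet


def volcano_plot(de_table: pd.DataFrame, p_threshold: float = 0.05,
                 lfc_threshold: float = 0.5, path=None):
    """Volcano: metastasis-up on the left (negative log2FC), primary-up right."""
    fig, ax = plt.subplots(figsize=(6, 5))
    tab = de_table.dropna(subset=["p_value"])
    colors = np.where(
        tab["de_class"] == UP_METASTASIS, "crimson",
        np.where(tab["de_class"] == UP_PRIMARY, "royalblue", "lightgray"),
    )
    ax.scatter(tab["log2fc"], -np.log10(tab["p_value"]), s=12, c=colors,
               alpha=0.7, linewidths=0)
    ax.axhline(-np.log10(p_threshold), ls="--", c="k", lw=0.8)
    ax.axvline(lfc_threshold, ls="--", c="k", lw=0.8)
    ax.axvline(-lfc_threshold, ls="--", c="k", lw=0.8)
    ax.set_xlabel("log2 fold change (primary − metastasis)")
    ax.set_ylabel("−log10 p")
    ax.set_title("Differential expression, pooled primaries vs metastases")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def consensus_heatmap(consensus: pd.DataFrame, labels: pd.Series | None = None,
                      path=None):
    order = labels.sort_values().index if labels is not None else consensus.index
    C = consensus.loc[order, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    sns.heatmap(C, cmap="viridis", vmin=0, vmax=1, square=True, ax=ax,
                xticklabels=False, yticklabels=False,
                cbar_kws={"label": "co-clustering frequency"})
    ax.set_title("Consensus matrix")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def sweep_curves(sweep_table: pd.DataFrame, selected_k: int | None = None,
                 path=None):
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, col in zip(axes, ("cophenetic", "dispersion")):
        ax.plot(sweep_table.index, sweep_table[col], "o-")
        if selected_k is not None:
            ax.axvline(selected_k, ls="--", c="crimson", lw=0.8)
        ax.set_xlabel("rank k")
        ax.set_ylabel(col)
    fig.suptitle("Rank selection")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores over valid entries (mean 0, sd 1 per protein)."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    return values.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0)


def candidate_heatmap(matrix: IntensityMatrix, protein_ids: list[str],
                      labels: pd.Series | None = None, path=None):
    """Z-scored expression of selected proteins, samples ordered by cluster."""
    present = [p for p in protein_ids if p in matrix.values.index]
    data = zscore_rows(matrix.values.loc[present])
    if labels is not None:
        data = data[labels.sort_values().index]
    fig, ax = plt.subplots(figsize=(7, max(3, 0.12 * len(present))))
    sns.heatmap(data, cmap="vlag", center=0, ax=ax, xticklabels=False,
                yticklabels=len(present) <= 40,
                cbar_kws={"label": "row z-score"})
    ax.set_title("Cluster-relevant protein expression (z-scored)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def pca_scatter(scores: pd.DataFrame, sheet: SampleSheet,
                explained: np.ndarray | None = None, path=None):
    """PC1/PC2 scatter, primaries vs metastases, localization codes as text."""
    fig, ax = plt.subplots(figsize=(6, 5))
    meta = sheet.table.set_index("sample_id").loc[scores.index]
    for tissue, color in (("primary", "royalblue"), ("metastasis", "crimson")):
        mask = meta["tissue_type"] == tissue
        ax.scatter(scores.loc[mask.values, "PC1"], scores.loc[mask.values, "PC2"],
                   c=color, label=tissue, s=30, alpha=0.8)
    for sid in scores.index:
        loc = meta.loc[sid, "localization"]
        if loc:
            ax.annotate(loc, (scores.loc[sid, "PC1"], scores.loc[sid, "PC2"]),
                        fontsize=6, xytext=(2, 2), textcoords="offset points")
    if explained is not None and len(explained) >= 2:
        ax.set_xlabel(f"PC1 ({100 * explained[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * explained[1]:.1f}%)")
    else:
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
    ax.legend()
    ax.set_title("PCA of samples")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def render_report(result, outdir) -> list[Path]:
    """Write the four standard figures for a finished run."""
    from .pipeline import sweep_table as _sweep_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    paths = []
    p = outdir / "volcano.png"
    volcano_plot(result.de_table, cfg.p_threshold, cfg.lfc_threshold, path=p)
    paths.append(p)
    p = outdir / "consensus.png"
    consensus_heatmap(result.consensus.consensus, result.consensus.labels, path=p)
    paths.append(p)
    p = outdir / "rank_selection.png"
    sweep_curves(_sweep_table(result.sweep), result.selected_k, path=p)
    paths.append(p)
    p = outdir / "relevance_heatmap.png"
    candidate_heatmap(result.normalized, result.relevance.selected,
                      result.consensus.labels, path=p)
    paths.append(p)
    return paths
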