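"""Matplotlib exports: QC scatter plots, stability violins, marker heat maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_genes_umi", "plot_mito_ribo", "plot_violin", "plot_heatmap"]


def plot_genes_umi(qc_table: pd.DataFrame, path) -> Path:
    """Detected genes vs total UMI per cell."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(qc_table["total_umi"], qc_table["detected_genes"], s=8, alpha=0.6)
    ax.set_xlabel("total UMI per cell")
    ax.set_ylabel("detected genes per cell")
    ax.set_title("Detected genes vs sequencing depth")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_mito_ribo(qc_table: pd.DataFrame, path) -> Path:
    """Mito% vs ribo% per cell, colored by detected genes."""
    table = qc_table.dropna(subset=["mito_gene_pct", "ribo_gene_pct"])
    fig, ax = plt.subplots(figsize=(5.5, 4))
    sc = ax.scatter(
        table["ribo_gene_pct"],
        table["mito_gene_pct"],
        c=table["detected_genes"],
        s=8,
        cmap="viridis",
    )
    fig.colorbar(sc, ax=ax, label="detected genes")
    ax.set_xlabel("% ribosomal of detected genes")
    ax.set_ylabel("% mitochondrial of detected genes")
    ax.set_title("Mitochondrial vs ribosomal gene content")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_violin(violin_table: pd.DataFrame, path) -> Path:
    """Violin plot of CSS and silhouette distributions (per k if several)."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=False)
    for ax, metric, ylim in zip(axes, ("css", "silhouette"), ((0, 1.02), (-1, 1))):
        sub = violin_table[violin_table["metric"] == metric]
        ks = sorted(sub["k"].unique())
        data = [sub.loc[sub["k"] == k, "value"].to_numpy() for k in ks]
        data = [d for d in data if len(d)]
        if data:
            ax.violinplot(data, showmedians=True)
            ax.set_xticks(range(1, len(ks) + 1), [str(k) for k in ks])
        ax.set_xlabel("k")
        ax.set_ylabel(metric)
        ax.set_ylim(*ylim)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_heatmap(matrix: pd.DataFrame, path) -> Path:
    """Standardised expression heat map (genes x cells, pre-ordered)."""
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.2 * len(matrix))))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=6)
    ax.set_xticks([])
    ax.set_xlabel("cells (ordered by cluster)")
    fig.colorbar(im, ax=ax, label="row z-score of log2(CPM+1)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
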