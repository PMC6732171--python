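"""Cluster-specific gene signatures and heat-map exports.

Differential signal across clusters is assessed gene-by-gene with a one-way
ANOVA on log2(CPM + 1), Benjamini-Hochberg corrected over the tested genes.
This is a deliberate functional substitute for count-model (quasi-likelihood)
ANOVA-like tests: the contract consumed downstream is per-gene
across-cluster signal plus an FDR, not a particular count model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .clusterers import Partition
from .matrix_io import CountMatrix

__all__ = ["cpm", "anova_like", "top_markers", "heatmap_export"]


def cpm(m: CountMatrix) -> np.ndarray:
    """Counts-per-million matrix (genes x cells); columns sum to 1e6."""
    totals = m.total_umi().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"CPM undefined for zero-total-UMI cells: {list(m.cell_ids[zero][:5])}"
        )
    return m.counts.toarray() * (1e6 / totals)


def _align_partition(m: CountMatrix, partition: Partition) -> tuple[CountMatrix, Partition]:
    if list(partition.cell_ids) != list(m.cell_ids):
        pos = m.cell_index()
        missing = [c for c in partition.cell_ids if c not in pos]
        if missing:
            raise ValueError(f"partition cells absent from matrix: {missing[:5]}")
        m = m.subset_cells(np.array([pos[c] for c in partition.cell_ids]))
    return m, partition


def anova_like(
    m: CountMatrix,
    partition: Partition,
    min_cells_expressing: int = 3,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA across clusters on log2(CPM+1).

    Genes expressed (count > 0) in at least ``min_cells_expressing`` cells
    are tested; the rest appear with ``tested=False`` and NaN statistics.
    BH correction runs over tested genes only. ``best_cluster`` is the
    cluster with the highest mean CPM. Requires k >= 2 and every cluster to
    hold at least 2 cells.
    """
    m, partition = _align_partition(m, partition)
    k = partition.k
    if k < 2:
        raise ValueError("anova_like requires at least 2 clusters")
    sizes = np.bincount(partition.labels, minlength=k + 1)[1:]
    if (sizes < 2).any():
        small = [c + 1 for c in np.flatnonzero(sizes < 2)]
        raise ValueError(
            f"clusters with fewer than 2 cells (within-group variance "
            f"undefined): {small}"
        )
    cpm_matrix = cpm(m)
    log_expr = np.log2(cpm_matrix + 1.0)
    expressed_cells = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    tested = expressed_cells >= min_cells_expressing

    groups_log = [log_expr[:, partition.labels == c] for c in range(1, k + 1)]
    cluster_means = np.column_stack([cpm_matrix[:, partition.labels == c].mean(axis=1)
                                     for c in range(1, k + 1)])
    stat = np.full(m.n_genes, np.nan)
    pval = np.full(m.n_genes, np.nan)
    if tested.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            f_res = stats.f_oneway(*[g[tested] for g in groups_log], axis=1)
        s = np.asarray(f_res.statistic, dtype=float)
        p = np.asarray(f_res.pvalue, dtype=float)
        # constant genes (zero variance everywhere) -> no signal by convention
        degenerate = ~np.isfinite(s)
        s[degenerate] = 0.0
        p[degenerate] = 1.0
        stat[tested] = s
        pval[tested] = p
    fdr = np.full(m.n_genes, np.nan)
    if tested.any():
        from statsmodels.stats.multitest import multipletests

        fdr[tested] = multipletests(pval[tested], method="fdr_bh")[1]
    result = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "tested": tested,
            "statistic": stat,
            "p_value": pval,
            "fdr": fdr,
            "best_cluster": np.argmax(cluster_means, axis=1) + 1,
        }
    )
    for c in range(1, k + 1):
        result[f"mean_cpm_cluster_{c}"] = cluster_means[:, c - 1]
    return result


def top_markers(
    results: pd.DataFrame,
    per_cluster_n: int | None = None,
    fdr_threshold: float | None = 0.05,
) -> dict[int, list]:
    """Ranked marker genes per cluster from an :func:`anova_like` table.

    A gene belongs to the list of its ``best_cluster`` if its fdr is strictly
    below ``fdr_threshold``; lists are ordered by ascending fdr, then
    descending statistic, then gene id, and capped at ``per_cluster_n``.
    """
    if results.empty:
        raise ValueError("empty results table")
    clusters = sorted(
        int(c) for c in results["best_cluster"].dropna().unique()
    )
    out: dict[int, list] = {c: [] for c in clusters}
    passing = results[results["tested"]].copy()
    if fdr_threshold is not None:
        passing = passing[passing["fdr"] < fdr_threshold]
    passing = passing.sort_values(
        ["fdr", "statistic", "gene_id"], ascending=[True, False, True]
    )
    for c in clusters:
        genes = passing.loc[passing["best_cluster"] == c, "gene_id"].tolist()
        out[c] = genes[:per_cluster_n] if per_cluster_n is not None else genes
    return out


def heatmap_export(
    m: CountMatrix,
    partition: Partition,
    genes,
) -> tuple[pd.DataFrame, dict]:
    """Ordered heat-map matrix plus per-gene cell-expression tables.

    Cells are ordered by cluster label then barcode. Genes are ordered by
    average-linkage hierarchical clustering (Euclidean) of row-standardised
    log2(CPM+1); zero-variance rows standardise to zeros. Returns the ordered
    standardised matrix (genes x cells) and, per requested gene, a
    ``(cell_id, cluster, cpm)`` long table.
    """
    m, partition = _align_partition(m, partition)
    genes = list(genes)
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    missing = [g for g in genes if g not in gene_pos]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    order = np.lexsort((partition.cell_ids.astype(str), partition.labels))
    cells_ordered = partition.cell_ids[order]
    clusters_ordered = partition.labels[order]

    cpm_matrix = cpm(m)
    rows = np.array([gene_pos[g] for g in genes])
    log_expr = np.log2(cpm_matrix[rows][:, order] + 1.0)
    mean = log_expr.mean(axis=1, keepdims=True)
    std = log_expr.std(axis=1, keepdims=True)
    standardized = np.divide(
        log_expr - mean, std, out=np.zeros_like(log_expr), where=std > 0
    )
    if len(genes) > 2:
        from scipy.cluster.hierarchy import average, leaves_list
        from scipy.spatial.distance import pdist

        gene_order = leaves_list(average(pdist(standardized, metric="euclidean")))
    else:
        gene_order = np.arange(len(genes))
    matrix = pd.DataFrame(
        standardized[gene_order],
        index=[genes[i] for i in gene_order],
        columns=cells_ordered,
    )
    per_gene = {}
    for g in genes:
        per_gene[g] = pd.DataFrame(
            {
                "cell_id": cells_ordered,
                "cluster": clusters_ordered,
                "cpm": cpm_matrix[gene_pos[g]][order],
            }
        )
    return matrix, per_gene
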