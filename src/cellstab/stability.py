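"""Cluster-stability analysis under jackknife resampling.

The central quantity is the per-cell **cell stability score (CSS)**: how
persistently a cell stays with its reference co-cluster when the dataset is
perturbed by removing a random fraction ``f`` of cells and re-clustering.
For cell *i* retained in perturbation run *b*,

    A      = (reference cluster of i)  ∩  retained cells of run b
    B      = run-b cluster containing i
    J(i,b) = |A ∩ B| / |A ∪ B|            (both sets contain i)

and ``css(i)`` is the mean of ``J(i, b)`` over the runs that retain *i*
(optionally, the fraction of runs with ``J >= threshold``). CSS lies in
(0, 1]: self-membership forces positivity, and it reaches 1 exactly when
run clusters restricted-reproduce the reference co-cluster set.

Cluster-level stability follows the bootstrap/clusterboot convention: for a
reference cluster *C*, the per-run score is the maximum Jaccard overlap
between ``C ∩ retained`` and any run cluster, averaged over runs where *C*
survives.

The run schedule is fully reproducible: run *b* draws its removed subset and
its clusterer seed from ``master_seed + b`` alone, so any execution order
(or parallel execution) yields identical results. Defaults are ``f = 0.1``
and ``B = 160`` perturbations; at least 100 perturbations are recommended
for a well-estimated CSS.

:class:`StabilityAnalysis` is the modelling-object entry point: construct it
from a count matrix and a clusterer spec, call :meth:`~StabilityAnalysis.fit`
and inspect the returned :class:`StabilityResults`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .clusterers import (
    ClustererSpec,
    Partition,
    cluster,
    labels_from_embedding,
    pca_scores,
    transform_counts,
)
from .matrix_io import CountMatrix

__all__ = [
    "PermutationRun",
    "StabilityResults",
    "StabilityAnalysis",
    "SweepResult",
    "permute_and_cluster",
    "cell_stability_score",
    "cluster_stability",
    "silhouette_scores",
    "silhouette_from_embedding",
    "css_sweep",
    "violin_export",
]


@dataclass
class PermutationRun:
    """One perturbation: retained cell subset + its partition + seed."""

    run_index: int
    seed: int
    retained_cell_ids: np.ndarray
    partition: Partition

    def __post_init__(self) -> None:
        self.retained_cell_ids = np.asarray(self.retained_cell_ids, dtype=object)
        if list(self.partition.cell_ids) != list(self.retained_cell_ids):
            raise ValueError("partition must cover exactly the retained cells")


def _check_schedule(n: int, spec: ClustererSpec, B: int, f: float) -> int:
    if not (0.0 < f < 1.0):
        raise ValueError(f"removal fraction f must be in (0, 1), got {f}")
    if B < 1:
        raise ValueError("B must be >= 1")
    n_remove = math.floor(f * n)
    n_keep = n - n_remove
    minimum = 2
    if spec.engine == "kmeans_log" and spec.k is not None:
        minimum = max(minimum, spec.k)
    if spec.engine == "graph_community":
        minimum = max(minimum, spec.n_neighbors + 1)
    if n_keep < minimum:
        raise ValueError(
            f"retained set of {n_keep} cells is below the clusterer minimum "
            f"of {minimum}"
        )
    return n_remove


def _retained_indices(n: int, n_remove: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    removed = rng.choice(n, size=n_remove, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[removed] = False
    return np.flatnonzero(keep)


def permute_and_cluster(
    m: CountMatrix,
    spec: ClustererSpec,
    B: int = 160,
    f: float = 0.1,
    master_seed: int = 0,
) -> list[PermutationRun]:
    """B perturbation runs: remove ``floor(f*n)`` random cells, re-cluster.

    Run ``b`` (1-based) derives all randomness from the child seed
    ``master_seed + b``: both the removed subset and the clusterer seed.
    """
    spec.validate(n_cells=m.n_cells)
    n = m.n_cells
    n_remove = _check_schedule(n, spec, B, f)
    x = transform_counts(m, spec.transform) if spec.engine != "external" else None
    runs: list[PermutationRun] = []
    for b in range(1, B + 1):
        child = master_seed + b
        idx = _retained_indices(n, n_remove, child)
        retained_ids = m.cell_ids[idx]
        if spec.engine == "external":
            part = cluster(m.subset_cells(idx), spec, seed=child)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                emb = pca_scores(x[:, idx].T, spec.n_pcs)
                labels = labels_from_embedding(emb, spec, seed=child)
            part = Partition(retained_ids, labels)
        runs.append(
            PermutationRun(
                run_index=b, seed=child, retained_cell_ids=retained_ids, partition=part
            )
        )
    return runs


def _run_contingency(
    reference: Partition,
    run: PermutationRun,
    cell_pos: dict,
):
    """Counts n[r, l] of retained cells by (reference label r, run label l)."""
    ref_k = reference.k
    run_k = run.partition.k
    table = np.zeros((ref_k + 1, run_k + 1), dtype=np.int64)
    positions = np.empty(len(run.retained_cell_ids), dtype=np.int64)
    for j, c in enumerate(run.retained_cell_ids):
        if c not in cell_pos:
            raise ValueError(f"run {run.run_index} contains unknown cell {c!r}")
        positions[j] = cell_pos[c]
    r = reference.labels[positions]
    l = run.partition.labels
    np.add.at(table, (r, l), 1)
    return table, positions, r, l


def cell_stability_score(
    reference: Partition,
    runs: list[PermutationRun],
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell CSS and retention counts, aligned to ``reference.cell_ids``.

    With ``threshold=None`` (the reference behaviour) CSS is the mean
    Jaccard index over retaining runs; with a threshold it is the fraction
    of retaining runs whose Jaccard index is >= threshold. Cells never
    retained get NaN (flagged undefined, never silently zero).
    """
    n = len(reference.cell_ids)
    cell_pos = {c: i for i, c in enumerate(reference.cell_ids)}
    acc = np.zeros(n)
    n_retained = np.zeros(n, dtype=np.int64)
    for run in runs:
        table, positions, r, l = _run_contingency(reference, run, cell_pos)
        a = table.sum(axis=1)  # |ref cluster ∩ retained|
        b = table.sum(axis=0)  # |run cluster|
        inter = table[r, l].astype(float)
        union = a[r] + b[l] - inter
        jacc = inter / union
        if threshold is None:
            np.add.at(acc, positions, jacc)
        else:
            np.add.at(acc, positions, (jacc >= threshold).astype(float))
        np.add.at(n_retained, positions, 1)
    with np.errstate(invalid="ignore"):
        css = np.where(n_retained > 0, acc / np.maximum(n_retained, 1), np.nan)
    return css, n_retained


def cluster_stability(
    reference: Partition, runs: list[PermutationRun]
) -> pd.Series:
    """Per-reference-cluster mean-max-Jaccard stability (clusterboot style).

    ``gamma(C, b) = max_D |C ∩ retained_b ∩ D| / |(C ∩ retained_b) ∪ D|``
    over run-b clusters D, averaged over the runs where C retains at least
    one cell. Clusters removed in every run get NaN.
    """
    cell_pos = {c: i for i, c in enumerate(reference.cell_ids)}
    ref_k = reference.k
    acc = np.zeros(ref_k + 1)
    seen = np.zeros(ref_k + 1, dtype=np.int64)
    for run in runs:
        table, _, _, _ = _run_contingency(reference, run, cell_pos)
        a = table.sum(axis=1).astype(float)
        b = table.sum(axis=0).astype(float)
        for r in range(1, ref_k + 1):
            if a[r] == 0:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                gammas = table[r, 1:] / (a[r] + b[1:] - table[r, 1:])
            acc[r] += float(np.max(gammas)) if gammas.size else 0.0
            seen[r] += 1
    values = np.where(seen[1:] > 0, acc[1:] / np.maximum(seen[1:], 1), np.nan)
    return pd.Series(values, index=pd.RangeIndex(1, ref_k + 1, name="cluster"))


def silhouette_from_embedding(embedding: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Standard per-sample silhouette; singleton clusters and degenerate
    zero-distance data score 0 by convention."""
    from sklearn.metrics import silhouette_samples

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster (k=1)")
    if embedding.shape[1] == 0 or not np.any(np.ptp(embedding, axis=0) > 0):
        return np.zeros(len(labels))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = silhouette_samples(embedding, labels)
    return np.nan_to_num(values, nan=0.0)


def silhouette_scores(
    m: CountMatrix, partition: Partition, spec: ClustererSpec
) -> np.ndarray:
    """Per-cell silhouette in the same transform/PCA space the clusterer used."""
    if list(partition.cell_ids) != list(m.cell_ids):
        pos = m.cell_index()
        idx = np.array([pos[c] for c in partition.cell_ids])
        m = m.subset_cells(idx)
    embedding = pca_scores(transform_counts(m, spec.transform).T, spec.n_pcs)
    return silhouette_from_embedding(embedding, partition.labels)


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------


@dataclass
class StabilityResults:
    """Output of one stability analysis at fixed clusterer settings.

    Attributes
    ----------
    reference
        Partition of the full, unperturbed matrix (the anchor).
    css, n_retained, silhouette
        Per-cell arrays aligned to ``reference.cell_ids``; ``css`` is NaN for
        cells never retained.
    cluster_stability
        Per-reference-cluster mean-max-Jaccard stability.
    params
        The run schedule (B, f, seeds, clusterer spec) for reproducibility.
    """

    reference: Partition
    css: np.ndarray
    n_retained: np.ndarray
    silhouette: np.ndarray
    cluster_stability: pd.Series
    params: dict = field(default_factory=dict)

    @property
    def mean_css(self) -> float:
        return float(np.nanmean(self.css))

    @property
    def mean_silhouette(self) -> float:
        return float(np.nanmean(self.silhouette))

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.reference.cell_ids,
                "cluster": self.reference.labels,
                "css": self.css,
                "n_retained": self.n_retained,
                "silhouette": self.silhouette,
            }
        )

    def violin_table(self) -> pd.DataFrame:
        return violin_export(self)

    def summary(self) -> str:
        lines = [
            "Cluster stability analysis",
            "==========================",
            f"cells: {len(self.reference.cell_ids)}   clusters: {self.reference.k}",
            f"perturbations B={self.params.get('B')}  removal f={self.params.get('f')}"
            f"  master_seed={self.params.get('master_seed')}",
            f"engine: {self.params.get('engine')}  transform: "
            f"{self.params.get('transform')}",
            "",
            f"mean CSS        : {self.mean_css:8.4f}",
            f"median CSS      : {float(np.nanmedian(self.css)):8.4f}",
            f"mean silhouette : {self.mean_silhouette:8.4f}",
            f"cells never retained: {int(np.sum(self.n_retained == 0))}",
            "",
            "per-cluster stability (mean max Jaccard):",
        ]
        sizes = pd.Series(self.reference.labels).value_counts().sort_index()
        for c, val in self.cluster_stability.items():
            mean_css_c = float(np.nanmean(self.css[self.reference.labels == c]))
            lines.append(
                f"  cluster {c:>2}: n={int(sizes[c]):>5}  stability={val:6.4f}"
                f"  mean CSS={mean_css_c:6.4f}"
            )
        return "\n".join(lines)

    def save(self, out_dir) -> Path:
        """Persist reference labels, per-cell scores, per-cluster stability,
        the violin table, and a JSON params block."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.reference.save_csv(out / "reference_labels.csv")
        self.scores_frame().to_csv(out / "cell_scores.csv", index=False)
        self.cluster_stability.rename("stability").to_csv(out / "cluster_stability.csv")
        self.violin_table().to_csv(out / "violin_table.csv", index=False)
        with open(out / "params.json", "w") as fh:
            json.dump(self.params, fh, indent=2, default=str)
        return out


class StabilityAnalysis:
    """Perturbation-based cluster stability model for one count matrix.

    Parameters
    ----------
    m
        Count matrix (genes x cells), QC-filtered.
    spec
        Clusterer configuration shared by the reference clustering and every
        perturbation run.
    B
        Number of perturbation runs (>= 100 recommended, default 160).
    f
        Fraction of cells removed per run (default 0.1).
    css_threshold
        None for mean-Jaccard CSS; a value in (0, 1] switches to the
        fraction-of-runs-above-threshold variant.

    Examples
    --------
    >>> res = StabilityAnalysis(m, ClustererSpec(k=3), B=100).fit(master_seed=7)
    >>> print(res.summary())
    """

    def __init__(
        self,
        m: CountMatrix,
        spec: ClustererSpec,
        B: int = 160,
        f: float = 0.1,
        css_threshold: float | None = None,
    ) -> None:
        spec.validate(n_cells=m.n_cells)
        _check_schedule(m.n_cells, spec, B, f)
        self.m = m
        self.spec = spec
        self.B = B
        self.f = f
        self.css_threshold = css_threshold

    def fit(self, master_seed: int = 0, keep_runs: bool = False) -> StabilityResults:
        """Run the full schedule; bit-identical for identical master seeds."""
        reference = cluster(self.m, self.spec, seed=master_seed)
        runs = permute_and_cluster(
            self.m, self.spec, B=self.B, f=self.f, master_seed=master_seed
        )
        return self._assemble(reference, runs, master_seed, keep_runs)

    def _assemble(
        self,
        reference: Partition,
        runs: list[PermutationRun],
        master_seed: int,
        keep_runs: bool = False,
    ) -> StabilityResults:
        css, n_retained = cell_stability_score(
            reference, runs, threshold=self.css_threshold
        )
        if reference.k >= 2:
            silhouette = silhouette_scores(self.m, reference, self.spec)
        else:
            silhouette = np.full(len(reference.cell_ids), np.nan)
        result = StabilityResults(
            reference=reference,
            css=css,
            n_retained=n_retained,
            silhouette=silhouette,
            cluster_stability=cluster_stability(reference, runs),
            params={
                "B": self.B,
                "f": self.f,
                "master_seed": master_seed,
                "engine": self.spec.engine,
                "transform": self.spec.transform,
                "k": self.spec.k,
                "n_pcs": self.spec.n_pcs,
                "n_neighbors": self.spec.n_neighbors,
                "css_threshold": self.css_threshold,
                "run_seeds": [r.seed for r in runs],
            },
        )
        if keep_runs:
            result.runs = runs  # type: ignore[attr-defined]
        return result


# ---------------------------------------------------------------------------
# k sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Per-k stability summaries and the selected k."""

    table: pd.DataFrame
    best_k: int
    reports: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["CSS sweep over candidate k", "--------------------------"]
        lines.append(
            self.table.to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            )
        )
        lines.append(f"best k (max mean CSS, ties -> smallest): {self.best_k}")
        return "\n".join(lines)


def css_sweep(
    m: CountMatrix,
    spec: ClustererSpec,
    k_values,
    B: int = 160,
    f: float = 0.1,
    master_seed: int = 0,
    keep_reports: bool = False,
    css_threshold: float | None = None,
) -> SweepResult:
    """Stability run per candidate k; selects k with the highest mean CSS.

    For each k the full-matrix reference clustering (master seed) and the B
    perturbation runs are scored; ties in mean CSS go to the smallest k.
    The perturbation schedule (removed subsets) is shared across k, so the
    comparison is paired. Only k-taking engines are eligible.
    """
    k_values = [int(k) for k in k_values]
    if not k_values:
        raise ValueError("k_values must be non-empty")
    if spec.engine not in ("kmeans_log", "external"):
        raise ValueError("css_sweep requires an engine that takes k as input")
    rows = []
    reports: dict[int, StabilityResults] = {}
    shared: dict | None = None
    if spec.engine == "kmeans_log":
        # subset embeddings are k-independent: compute once, reuse per k
        x = transform_counts(m, spec.transform)
        n = m.n_cells
        n_remove = _check_schedule(n, replace(spec, k=max(k_values)), B, f)
        full_emb = pca_scores(x.T, spec.n_pcs)
        contexts = []
        for b in range(1, B + 1):
            child = master_seed + b
            idx = _retained_indices(n, n_remove, child)
            contexts.append((b, child, idx, pca_scores(x[:, idx].T, spec.n_pcs)))
        shared = {"full_emb": full_emb, "contexts": contexts}
    for k in sorted(k_values):
        spec_k = replace(spec, k=k)
        analysis = StabilityAnalysis(m, spec_k, B=B, f=f, css_threshold=css_threshold)
        if shared is not None:
            reference = Partition(
                m.cell_ids,
                labels_from_embedding(shared["full_emb"], spec_k, seed=master_seed),
            )
            runs = []
            for b, child, idx, emb in shared["contexts"]:
                retained_ids = m.cell_ids[idx]
                labels = labels_from_embedding(emb, spec_k, seed=child)
                runs.append(
                    PermutationRun(b, child, retained_ids, Partition(retained_ids, labels))
                )
            report = analysis._assemble(reference, runs, master_seed)
        else:
            report = analysis.fit(master_seed=master_seed)
        css = report.css[~np.isnan(report.css)]
        q1, q3 = np.percentile(css, [25, 75]) if css.size else (np.nan, np.nan)
        rows.append(
            {
                "k": k,
                "mean_css": report.mean_css,
                "median_css": float(np.median(css)) if css.size else np.nan,
                "iqr_css": float(q3 - q1),
                "mean_silhouette": report.mean_silhouette,
            }
        )
        if keep_reports:
            reports[k] = report
    table = pd.DataFrame(rows)
    best_row = table.sort_values(["mean_css", "k"], ascending=[False, True]).iloc[0]
    return SweepResult(table=table, best_k=int(best_row["k"]), reports=reports)


def violin_export(report: StabilityResults, k: int | None = None) -> pd.DataFrame:
    """Long-format (cell_id, metric, value, k) table for violin plots.

    Undefined (NaN) values are omitted; the omission count is recorded in
    ``df.attrs["n_omitted"]``.
    """
    if k is None:
        k = report.reference.k
    frames = []
    n_omitted = 0
    for metric, values in (("css", report.css), ("silhouette", report.silhouette)):
        mask = ~np.isnan(values)
        n_omitted += int(np.sum(~mask))
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": report.reference.cell_ids[mask],
                    "metric": metric,
                    "value": values[mask],
                    "k": k,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cell_id", "metric", "value", "k"]
    )
    out.attrs["n_omitted"] = n_omitted
    return out
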