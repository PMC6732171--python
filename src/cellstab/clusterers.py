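"""Uniform clusterer contract and built-in baseline engines.

The stability machinery is clusterer-agnostic: anything that maps a count
matrix to a :class:`Partition` can be perturbed and scored. Two baseline
engines are built in, mirroring the input conventions of the common
single-cell clusterers:

``kmeans_log``
    k-means (k-means++ init, 10 restarts, best inertia) on the top principal
    components of log10(count+1)-transformed cells — the convention of
    k-means-style engines that take k as input.
``graph_community``
    symmetrised unweighted kNN graph (Euclidean in the same PCA space) plus
    greedy modularity community detection, where k emerges from the data —
    the convention of agglomerative Louvain-style graph clusterers.

External clusterers plug in through a subprocess contract (invoked with a
matrix CSV path, k, and an output path; must write a ``barcode,label`` CSV)
or an in-process callable.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix_io import CountMatrix, save_counts

__all__ = [
    "Partition",
    "ClustererSpec",
    "transform_counts",
    "pca_scores",
    "embed_cells",
    "cluster",
    "labels_from_embedding",
    "propose_k",
]

TRANSFORMS = ("log10p1", "lognorm10k", "none")
ENGINES = ("kmeans_log", "graph_community", "external")

_DEGENERATE_VAR = 1e-12


@dataclass
class Partition:
    """Cell -> cluster-label assignment over a named, ordered cell set.

    Labels are canonical: integers ``1..k`` in order of first appearance,
    every label occupied. Label values carry no cross-run meaning; cluster
    identity is co-membership.
    """

    cell_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        raw = np.asarray(self.labels)
        if len(raw) != len(self.cell_ids):
            raise ValueError(
                f"{len(raw)} labels for {len(self.cell_ids)} cells"
            )
        if len(raw) == 0:
            raise ValueError("empty partition")
        # canonicalise to 1..k by first appearance
        mapping: dict = {}
        canonical = np.empty(len(raw), dtype=np.int64)
        for i, lab in enumerate(raw):
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            canonical[i] = mapping[lab]
        self.labels = canonical

    @property
    def k(self) -> int:
        return int(self.labels.max())

    def members(self, label: int) -> np.ndarray:
        return self.cell_ids[self.labels == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"barcode": self.cell_ids, "label": self.labels})

    def save_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def load_csv(cls, path) -> "Partition":
        df = pd.read_csv(path)
        return cls(df["barcode"].to_numpy(dtype=object), df["label"].to_numpy())


@dataclass
class ClustererSpec:
    """Configuration for one clustering engine.

    Parameters
    ----------
    engine
        ``kmeans_log`` (k required), ``graph_community`` (k emerges) or
        ``external``.
    k
        Number of clusters for k-based engines.
    transform
        Input transform: ``log10p1`` (log10(count+1)), ``lognorm10k``
        (ln(1 + 1e4 * count / cell_total)), or ``none``.
    n_pcs
        Number of principal components both engines operate in.
    n_neighbors
        kNN graph degree for ``graph_community``.
    seed
        Default seed; stability runs override it per permutation.
    external_cmd / external_fn
        External-clusterer contract (subprocess argv prefix, or a callable
        ``fn(matrix, k, seed) -> labels``).
    """

    engine: str = "kmeans_log"
    k: int | None = None
    transform: str = "log10p1"
    n_pcs: int = 10
    n_neighbors: int = 15
    seed: int = 0
    external_cmd: list | None = None
    external_fn: object | None = None

    def validate(self, n_cells: int | None = None) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine {self.engine!r}; choose from {ENGINES}")
        if self.transform not in TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.transform!r}; choose from {TRANSFORMS}"
            )
        if self.engine == "kmeans_log":
            if self.k is None or self.k < 2:
                raise ValueError("kmeans_log requires k >= 2")
            if n_cells is not None and self.k > n_cells:
                raise ValueError(f"k={self.k} exceeds cell count {n_cells}")
        if self.engine == "graph_community":
            if self.n_neighbors < 2:
                raise ValueError("n_neighbors must be >= 2")
            if n_cells is not None and self.n_neighbors >= n_cells:
                raise ValueError(
                    f"n_neighbors={self.n_neighbors} must be < cell count {n_cells}"
                )
        if self.engine == "external" and not (self.external_cmd or self.external_fn):
            raise ValueError("external engine needs external_cmd or external_fn")


def transform_counts(m: CountMatrix, transform: str = "log10p1") -> np.ndarray:
    """Dense transformed expression matrix (genes x cells).

    ``log10p1``: log10(count + 1). ``lognorm10k``: ln(1 + 10000 * count /
    cell total UMI) — global scaling normalisation with scale factor 10,000.
    ``none``: counts as float.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    dense = m.counts.toarray().astype(float)
    if transform == "none":
        return dense
    if transform == "log10p1":
        return np.log10(dense + 1.0)
    totals = dense.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"lognorm10k undefined for zero-total-UMI cells: "
            f"{list(m.cell_ids[zero][:5])}"
        )
    return np.log1p(1e4 * dense / totals)


def pca_scores(x_cells_by_features: np.ndarray, n_components: int) -> np.ndarray:
    """Principal-component scores (cells x P) of a dense matrix.

    Centered PCA via eigen-decomposition on the smaller side of the data;
    components with (near-)zero variance are dropped, so the returned width
    may be below ``n_components``. Returns a zero-width array for fully
    degenerate (constant) input.
    """
    x = np.asarray(x_cells_by_features, dtype=float)
    n, p = x.shape
    xc = x - x.mean(axis=0, keepdims=True)
    n_components = max(1, min(n_components, n - 1 if n > 1 else 1, p))
    if n <= p:
        gram = xc @ xc.T
        eigval, eigvec = np.linalg.eigh(gram)
        order = np.argsort(eigval)[::-1][:n_components]
        eigval = np.clip(eigval[order], 0.0, None)
        keep = eigval > _DEGENERATE_VAR
        scores = eigvec[:, order[keep]] * np.sqrt(eigval[keep])
    else:
        cov = xc.T @ xc
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1][:n_components]
        eigval = np.clip(eigval[order], 0.0, None)
        keep = eigval > _DEGENERATE_VAR
        scores = xc @ eigvec[:, order[keep]]
    return scores


def embed_cells(m: CountMatrix, spec: ClustererSpec) -> np.ndarray:
    """Cells x P embedding: transform then top-P PCA scores."""
    return pca_scores(transform_counts(m, spec.transform).T, spec.n_pcs)


def _kmeans_labels(embedding: np.ndarray, k: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(embedding)


def _graph_labels(embedding: np.ndarray, n_neighbors: int, seed: int) -> np.ndarray:
    import networkx as nx
    from sklearn.neighbors import NearestNeighbors

    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=min(n_neighbors, n - 1) + 1)
    nn.fit(embedding)
    _, idx = nn.kneighbors(embedding)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i, 1:]:
            graph.add_edge(i, int(j))
    communities = nx.community.greedy_modularity_communities(graph)
    labels = np.empty(n, dtype=np.int64)
    for lab, comm in enumerate(communities):
        for node in comm:
            labels[node] = lab
    return labels


def labels_from_embedding(
    embedding: np.ndarray, spec: ClustererSpec, seed: int | None = None
) -> np.ndarray:
    """Raw labels for an embedding under the spec's engine (no canonicalising)."""
    seed = spec.seed if seed is None else seed
    n = embedding.shape[0]
    if embedding.shape[1] == 0:
        warnings.warn(
            "all cells identical under the chosen transform; returning a "
            "single cluster",
            stacklevel=2,
        )
        return np.zeros(n, dtype=np.int64)
    if spec.engine == "kmeans_log":
        return _kmeans_labels(embedding, spec.k, seed)
    if spec.engine == "graph_community":
        return _graph_labels(embedding, spec.n_neighbors, seed)
    raise ValueError(f"engine {spec.engine!r} has no embedding-based path")


def _external_partition(m: CountMatrix, spec: ClustererSpec, seed: int) -> Partition:
    if spec.external_fn is not None:
        labels = spec.external_fn(m, spec.k, seed)
        return Partition(m.cell_ids, np.asarray(labels))
    with tempfile.TemporaryDirectory() as tmp:
        matrix_path = Path(tmp) / "matrix.csv"
        out_path = Path(tmp) / "labels.csv"
        save_counts(m, matrix_path, format="csv")
        argv = list(spec.external_cmd) + [
            str(matrix_path),
            str(spec.k if spec.k is not None else 0),
            str(out_path),
        ]
        subprocess.run(argv, check=True)
        part = Partition.load_csv(out_path)
    if set(part.cell_ids) != set(m.cell_ids):
        raise ValueError("external clusterer returned labels for different cells")
    # re-order to the matrix's cell order
    lookup = dict(zip(part.cell_ids, part.labels))
    return Partition(m.cell_ids, np.array([lookup[c] for c in m.cell_ids]))


def cluster(m: CountMatrix, spec: ClustererSpec, seed: int | None = None) -> Partition:
    """Cluster all cells of ``m`` under ``spec``; deterministic given seed.

    Degenerate all-identical input yields a single-cluster partition with a
    warning rather than an error, so perturbation runs never crash.
    """
    spec.validate(n_cells=m.n_cells)
    if m.n_cells < 2:
        raise ValueError("clustering needs at least 2 cells")
    seed = spec.seed if seed is None else seed
    if spec.engine == "external":
        return _external_partition(m, spec, seed)
    embedding = embed_cells(m, spec)
    return Partition(m.cell_ids, labels_from_embedding(embedding, spec, seed))


def propose_k(m: CountMatrix, spec: ClustererSpec | None = None) -> int:
    """Estimate the number of clusters with the graph-community engine."""
    if spec is None:
        spec = ClustererSpec(engine="graph_community")
    if spec.engine != "graph_community":
        spec = replace(spec, engine="graph_community", k=None)
    return cluster(m, spec).k
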