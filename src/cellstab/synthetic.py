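"""Deterministic synthetic UMI count matrices with planted structure.

The generator emulates a droplet scRNA-seq count table: gene-wise negative
binomial counts with log-normal baseline means, planted cell clusters that
differ only through cluster-specific marker genes (fold change applied to
the marker's baseline mean inside its cluster), mito (``mt-*``) and ribosomal
(``Rps*``/``Rpl*``) gene families recognisable by symbol, and optionally a
set of planted low-quality
"stressed" cells — columns overwritten with a low-complexity profile (few
detected genes, >50% of them mitochondrial, total UMI below 100) so that QC
filter tests have an exact planted truth.

Everything is a deterministic function of the spec (including its seed);
generating the same spec twice yields bit-identical matrices.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .matrix_io import CountMatrix, flag_genes, save_counts

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "presets", "write_fixture",
           "PRESET_NAMES"]

# stressed-cell profile: 15 mito + 10 other genes at 3 counts each
# -> 25 detected genes (< 100), 60% mito, total UMI 75 (< 100)
_STRESSED_MITO_GENES = 15
_STRESSED_OTHER_GENES = 10
_STRESSED_UNIT = 3


@dataclass(frozen=True)
class SyntheticSpec:
    """Frozen parameterisation of one synthetic dataset."""

    n_cells: int = 300
    n_genes: int = 2000
    k_true: int = 3
    cluster_proportions: tuple | None = None
    baseline_meanlog: float = 0.5
    baseline_sdlog: float = 1.2
    nb_dispersion: float = 0.1
    n_markers_per_cluster: int = 20
    marker_fold_change: float = 8.0
    marker_min_baseline: float = 0.5
    frac_mito_genes: float = 0.02
    frac_ribo_genes: float = 0.05
    n_stressed_cells: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.marker_fold_change <= 1:
            raise ValueError("marker_fold_change must be > 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        props = self.proportions()
        if len(props) != self.k_true or not np.isclose(sum(props), 1.0):
            raise ValueError("cluster_proportions must sum to 1, one per cluster")
        n_family = self.n_mito + self.n_ribo
        if self.k_true * self.n_markers_per_cluster > self.n_genes - n_family:
            raise ValueError("markers x clusters exceeds available genes")
        if self.n_stressed_cells:
            if self.n_mito < _STRESSED_MITO_GENES:
                raise ValueError(
                    f"stressed cells need >= {_STRESSED_MITO_GENES} mito genes"
                )
            if self.n_stressed_cells >= self.n_cells:
                raise ValueError("too many stressed cells")

    def proportions(self) -> tuple:
        if self.cluster_proportions is not None:
            return tuple(self.cluster_proportions)
        return tuple([1.0 / self.k_true] * self.k_true)

    @property
    def n_mito(self) -> int:
        return int(round(self.frac_mito_genes * self.n_genes))

    @property
    def n_ribo(self) -> int:
        return int(round(self.frac_ribo_genes * self.n_genes))


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated matrix."""

    true_labels: np.ndarray
    marker_gene_ids: dict
    stressed_cell_ids: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_labels": [int(v) for v in self.true_labels],
                "marker_gene_ids": {
                    str(k): list(v) for k, v in self.marker_gene_ids.items()
                },
                "stressed_cell_ids": list(self.stressed_cell_ids),
            },
            indent=2,
        )


def _gene_names(spec: SyntheticSpec) -> np.ndarray:
    names = []
    for i in range(spec.n_mito):
        names.append(f"mt-Sim{i + 1}")
    for i in range(spec.n_ribo):
        prefix = "Rps" if i % 2 == 0 else "Rpl"
        names.append(f"{prefix}{i + 1}")
    for i in range(spec.n_genes - spec.n_mito - spec.n_ribo):
        names.append(f"G{i + 1:05d}")
    return np.array(names, dtype=object)


def generate(spec: SyntheticSpec) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one synthetic count matrix plus its planted truth.

    Counts are gamma-Poisson (negative binomial) with
    ``var = mu + dispersion * mu^2``; marker genes get
    ``mu *= marker_fold_change`` inside their planted cluster. Markers are
    drawn among non-family genes with baseline mean >= ``marker_min_baseline``
    so that planted signatures are detectably expressed, matching how marker
    genes behave in real data.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gene_ids = _gene_names(spec)
    cell_ids = np.array([f"C{i + 1:05d}" for i in range(spec.n_cells)], dtype=object)

    # planted labels: contiguous blocks by proportion (order carries no info)
    props = np.array(spec.proportions())
    sizes = np.floor(props * spec.n_cells).astype(int)
    sizes[-1] = spec.n_cells - sizes[:-1].sum()
    labels = np.repeat(np.arange(1, spec.k_true + 1), sizes)

    baseline = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, spec.n_genes)

    n_family = spec.n_mito + spec.n_ribo
    candidates = np.arange(n_family, spec.n_genes)
    eligible = candidates[baseline[candidates] >= spec.marker_min_baseline]
    needed = spec.k_true * spec.n_markers_per_cluster
    if len(eligible) < needed:  # fall back to the most-expressed genes
        eligible = candidates[np.argsort(baseline[candidates])[::-1][:needed]]
    marker_idx = rng.choice(eligible, size=needed, replace=False) if needed else (
        np.array([], dtype=int)
    )
    marker_gene_ids: dict[int, list] = {}
    fold = np.ones((spec.n_genes, spec.k_true))
    for c in range(spec.k_true):
        idx = marker_idx[c * spec.n_markers_per_cluster:(c + 1) * spec.n_markers_per_cluster]
        marker_gene_ids[c + 1] = [str(g) for g in gene_ids[idx]]
        fold[idx, c] = spec.marker_fold_change

    mu = baseline[:, None] * fold[:, labels - 1]
    if spec.nb_dispersion > 0:
        shape = 1.0 / spec.nb_dispersion
        lam = rng.gamma(shape, mu * spec.nb_dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    # plant stressed cells by overwriting whole columns
    stressed_ids: list = []
    if spec.n_stressed_cells:
        stressed_pos = np.sort(
            rng.choice(spec.n_cells, size=spec.n_stressed_cells, replace=False)
        )
        other_start = n_family
        for pos in stressed_pos:
            counts[:, pos] = 0
            counts[:_STRESSED_MITO_GENES, pos] = _STRESSED_UNIT
            counts[
                other_start:other_start + _STRESSED_OTHER_GENES, pos
            ] = _STRESSED_UNIT
        stressed_ids = [str(c) for c in cell_ids[stressed_pos]]

    m = CountMatrix(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=sp.csr_matrix(counts),
        gene_symbols=gene_ids.copy(),
    )
    m = flag_genes(m)
    truth = SyntheticTruth(
        true_labels=labels,
        marker_gene_ids=marker_gene_ids,
        stressed_cell_ids=stressed_ids,
    )
    return m, truth


_PRESETS = {
    "easy2": SyntheticSpec(n_cells=100, n_genes=1000, k_true=2, seed=2),
    "easy3": SyntheticSpec(n_cells=300, n_genes=2000, k_true=3, seed=1),
    "easy5": SyntheticSpec(n_cells=400, n_genes=2000, k_true=5, seed=5),
    "null1": SyntheticSpec(
        n_cells=200, n_genes=1000, k_true=1, n_markers_per_cluster=0, seed=11
    ),
    "stressed_mix": SyntheticSpec(
        n_cells=300, n_genes=2000, k_true=3, n_stressed_cells=20, seed=7
    ),
}
PRESET_NAMES = tuple(_PRESETS)


def presets(name: str) -> SyntheticSpec:
    """Frozen named parameterisations used throughout the test suite."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None


def write_fixture(out_dir, m: CountMatrix, truth: SyntheticTruth) -> Path:
    """Write a 10x-style MTX directory plus a truth JSON."""
    out = Path(out_dir)
    save_counts(m, out, format="mtx_dir")
    (out / "truth.json").write_text(truth.to_json())
    return out
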