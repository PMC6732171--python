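"""Count-matrix I/O, gene annotation and mitochondrial/ribosomal flagging.

The in-memory container is :class:`CountMatrix`: a sparse genes x cells UMI
count matrix with gene and cell identifiers plus optional per-gene metadata
(display symbols, mito/ribo flags).  Readers accept 10x-style Matrix Market
directories (``matrix.mtx[.gz]`` + ``features.tsv``/``genes.tsv`` +
``barcodes.tsv``) and dense CSV/TSV tables with gene rows; writers produce
files that round-trip bit-identically through :func:`load_counts`.

Gene annotation maps ENSEMBL gene IDs to symbols using an Ensembl-dialect
GTF (or an equivalent table) and flags mitochondrial genes (symbol prefix
``MT-``/``mt-``) and cytosolic ribosomal protein genes (``Rps*``/``Rpl*``);
mitochondrial ribosomal ``Mrps*``/``Mrpl*`` genes are excluded by default
but can be included via ``include_mrp=True``.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "GeneAnnotation",
    "MatrixFormatError",
    "load_counts",
    "save_counts",
    "parse_gtf",
    "annotate_genes",
    "flag_genes",
    "flag_mito_ribo",
]

MITO_PATTERN = re.compile(r"^mt-", re.IGNORECASE)
RIBO_PATTERN = re.compile(r"^rp[sl]\d", re.IGNORECASE)
RIBO_MRP_PATTERN = re.compile(r"^m?rp[sl]\d", re.IGNORECASE)

_VERSION_SUFFIX = re.compile(r"\.\d+$")


class MatrixFormatError(ValueError):
    """Raised for malformed or inconsistent count-matrix / annotation input."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene record extracted from a GTF: ENSEMBL ID, symbol, chromosome."""

    ensembl_id: str
    symbol: str
    chromosome: str


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifiers and gene metadata.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    cell_ids
        Unique cell barcodes, one per column.
    counts
        Non-negative integer matrix of shape ``(len(gene_ids), len(cell_ids))``.
    gene_symbols
        Optional display names (filled by :func:`annotate_genes`).
    is_mito, is_ribo
        Optional per-gene boolean flags (filled by :func:`annotate_genes` or
        :func:`flag_genes`).
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    counts: sp.csr_matrix
    gene_symbols: np.ndarray | None = None
    is_mito: np.ndarray | None = None
    is_ribo: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise MatrixFormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise MatrixFormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise MatrixFormatError(f"duplicated {name} ids: {dupes[:10]}")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise MatrixFormatError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise MatrixFormatError("counts contain non-integer entries")
        if self.counts.dtype.kind != "i":
            self.counts = self.counts.astype(np.int64)
        for flag_name in ("is_mito", "is_ribo"):
            flag = getattr(self, flag_name)
            if flag is not None:
                flag = np.asarray(flag, dtype=bool)
                if flag.shape != (n_genes,):
                    raise MatrixFormatError(f"{flag_name} has wrong length")
                setattr(self, flag_name, flag)
        if self.gene_symbols is not None:
            self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
            if len(self.gene_symbols) != n_genes:
                raise MatrixFormatError("gene_symbols has wrong length")

    # -- convenience ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def has_flags(self) -> bool:
        return self.is_mito is not None and self.is_ribo is not None

    def total_umi(self) -> np.ndarray:
        """Per-cell total UMI (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        """New CountMatrix keeping the cells at integer positions ``index``."""
        index = np.asarray(index)
        return CountMatrix(
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[index],
            counts=self.counts[:, index],
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.copy(),
            is_mito=None if self.is_mito is None else self.is_mito.copy(),
            is_ribo=None if self.is_ribo is None else self.is_ribo.copy(),
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        """New CountMatrix keeping genes where boolean ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return CountMatrix(
            gene_ids=self.gene_ids[mask],
            cell_ids=self.cell_ids.copy(),
            counts=self.counts[mask, :],
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols[mask],
            is_mito=None if self.is_mito is None else self.is_mito[mask],
            is_ribo=None if self.is_ribo is None else self.is_ribo[mask],
        )

    def cell_index(self) -> dict:
        """Map barcode -> column position."""
        return {c: i for i, c in enumerate(self.cell_ids)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            list(self.gene_ids) == list(other.gene_ids)
            and list(self.cell_ids) == list(other.cell_ids)
            and (self.counts != other.counts).nnz == 0
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_one(directory: Path, names: list[str], what: str) -> Path:
    for name in names:
        for candidate in (directory / name, directory / f"{name}.gz"):
            if candidate.exists():
                return candidate
    raise MatrixFormatError(
        f"missing {what} file in {directory} (looked for {', '.join(names)})"
    )


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "mtx_dir"
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt", ".tab"):
        return "tsv"
    raise MatrixFormatError(f"cannot infer format of {path}; pass format explicitly")


def load_counts(
    path,
    format: str | None = None,
    cells_as_rows: bool = False,
) -> CountMatrix:
    """Read a count matrix from a 10x-style MTX directory or a dense CSV/TSV.

    Parameters
    ----------
    path
        MTX directory or delimited text file. Dense files must carry gene ids
        in the first column and cell barcodes in the header (set
        ``cells_as_rows=True`` for the transposed layout).
    format
        One of ``{"mtx_dir", "csv", "tsv"}``; inferred from ``path`` if None.
    """
    path = Path(path)
    if not path.exists():
        raise MatrixFormatError(f"input path does not exist: {path}")
    fmt = format or _infer_format(path)
    if fmt == "mtx_dir":
        matrix_file = _find_one(path, ["matrix.mtx"], "matrix")
        features_file = _find_one(path, ["features.tsv", "genes.tsv"], "features/genes")
        barcodes_file = _find_one(path, ["barcodes.tsv"], "barcodes")
        with _open_maybe_gz(matrix_file) as fh:
            mat = mmread(fh)
        feat = pd.read_csv(features_file, sep="\t", header=None, dtype=str)
        barcodes = pd.read_csv(barcodes_file, sep="\t", header=None, dtype=str)[0]
        gene_ids = feat[0].to_numpy(dtype=object)
        symbols = feat[1].to_numpy(dtype=object) if feat.shape[1] > 1 else None
        counts = sp.csr_matrix(mat)
        if counts.shape != (len(gene_ids), len(barcodes)):
            raise MatrixFormatError(
                f"matrix shape {counts.shape} disagrees with "
                f"{len(gene_ids)} features x {len(barcodes)} barcodes"
            )
        return CountMatrix(
            gene_ids=gene_ids,
            cell_ids=barcodes.to_numpy(dtype=object),
            counts=counts,
            gene_symbols=symbols,
        )
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        table = pd.read_csv(path, sep=sep, index_col=0)
        if cells_as_rows:
            table = table.T
        values = table.to_numpy()
        if values.size and (values < 0).any():
            raise MatrixFormatError("counts contain negative entries")
        return CountMatrix(
            gene_ids=table.index.to_numpy(dtype=object),
            cell_ids=table.columns.to_numpy(dtype=object),
            counts=sp.csr_matrix(values),
        )
    raise MatrixFormatError(f"unknown format {fmt!r}")


def save_counts(m: CountMatrix, path, format: str | None = None) -> Path:
    """Write ``m`` so that :func:`load_counts` reproduces it exactly.

    ``mtx_dir`` writes an uncompressed 10x-style triplet directory; ``csv`` /
    ``tsv`` write a dense table with gene rows.
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise MatrixFormatError("refusing to write a degenerate (empty) matrix")
    path = Path(path)
    fmt = format or ("mtx_dir" if path.suffix == "" else _infer_format(path))
    if fmt == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "matrix.mtx", "wb") as fh:
            mmwrite(fh, sp.coo_matrix(m.counts), field="integer")
        symbols = m.gene_symbols if m.gene_symbols is not None else m.gene_ids
        feat = pd.DataFrame(
            {0: m.gene_ids, 1: symbols, 2: ["Gene Expression"] * m.n_genes}
        )
        feat.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(m.cell_ids).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
        return path
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        dense = pd.DataFrame(
            m.counts.toarray(), index=m.gene_ids, columns=m.cell_ids
        )
        dense.index.name = "gene"
        dense.to_csv(path, sep=sep)
        return path
    raise MatrixFormatError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_ATTR_GENE_ID = re.compile(r'gene_id "([^"]+)"')
_ATTR_GENE_NAME = re.compile(r'gene_name "([^"]+)"')


def parse_gtf(path) -> pd.DataFrame:
    """Extract gene records (ensembl_id, symbol, chromosome) from an Ensembl GTF.

    ``gene`` feature lines are preferred; if the file has none (e.g. a
    transcript-only GTF) the first line seen per gene_id is used. Malformed
    lines raise :class:`MatrixFormatError` with the 1-based line number.
    """
    records: dict[str, GeneAnnotation] = {}
    fallback: dict[str, GeneAnnotation] = {}
    with _open_maybe_gz(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise MatrixFormatError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            id_match = _ATTR_GENE_ID.search(fields[8])
            if id_match is None:
                raise MatrixFormatError(
                    f"malformed GTF line {lineno}: no gene_id attribute"
                )
            gene_id = _VERSION_SUFFIX.sub("", id_match.group(1))
            name_match = _ATTR_GENE_NAME.search(fields[8])
            symbol = name_match.group(1) if name_match else gene_id
            rec = GeneAnnotation(gene_id, symbol, fields[0])
            if fields[2] == "gene":
                records.setdefault(gene_id, rec)
            else:
                fallback.setdefault(gene_id, rec)
    chosen = records if records else fallback
    return pd.DataFrame(
        {
            "ensembl_id": [r.ensembl_id for r in chosen.values()],
            "symbol": [r.symbol for r in chosen.values()],
            "chromosome": [r.chromosome for r in chosen.values()],
        }
    )


def flag_mito_ribo(
    symbols, include_mrp: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (is_mito, is_ribo) arrays from gene symbols.

    Mitochondrial: case-insensitive ``MT-`` prefix. Ribosomal: ``Rps*``/``Rpl*``
    (plus ``Mrps*``/``Mrpl*`` when ``include_mrp``). The two sets are disjoint.
    """
    ribo_pattern = RIBO_MRP_PATTERN if include_mrp else RIBO_PATTERN
    symbols = [str(s) for s in symbols]
    is_mito = np.array([bool(MITO_PATTERN.match(s)) for s in symbols])
    is_ribo = np.array(
        [bool(ribo_pattern.match(s)) and not MITO_PATTERN.match(s) for s in symbols]
    )
    return is_mito, is_ribo


def annotate_genes(m: CountMatrix, annotation, include_mrp: bool = False) -> CountMatrix:
    """Fill gene symbols from a GTF (path) or annotation table and set flags.

    Gene ids are matched with ENSEMBL version suffixes stripped. Unmapped
    genes keep their id as symbol. Duplicate symbols after mapping are
    disambiguated by appending ``:ensembl_id``. Counts, dimensions and order
    are never modified.
    """
    if isinstance(annotation, (str, Path)):
        table = parse_gtf(annotation)
    else:
        table = pd.DataFrame(annotation)
        if "ensembl_id" not in table.columns or "symbol" not in table.columns:
            raise MatrixFormatError(
                "annotation table needs 'ensembl_id' and 'symbol' columns"
            )
    mapping = dict(
        zip(
            table["ensembl_id"].map(lambda s: _VERSION_SUFFIX.sub("", str(s))),
            table["symbol"].astype(str),
        )
    )
    stripped = [_VERSION_SUFFIX.sub("", str(g)) for g in m.gene_ids]
    symbols = np.array(
        [mapping.get(g, orig) for g, orig in zip(stripped, m.gene_ids)], dtype=object
    )
    n_mapped = sum(g in mapping for g in stripped)
    if n_mapped == 0:
        warnings.warn(
            "no gene ids matched the annotation; symbols left as ids", stacklevel=2
        )
    # disambiguate duplicated symbols so downstream tables key uniquely
    counts_by_symbol = pd.Series(symbols).value_counts()
    dup_symbols = set(counts_by_symbol[counts_by_symbol > 1].index)
    if dup_symbols:
        symbols = np.array(
            [
                f"{s}:{g}" if s in dup_symbols else s
                for s, g in zip(symbols, m.gene_ids)
            ],
            dtype=object,
        )
    is_mito, is_ribo = flag_mito_ribo(symbols, include_mrp=include_mrp)
    return CountMatrix(
        gene_ids=m.gene_ids.copy(),
        cell_ids=m.cell_ids.copy(),
        counts=m.counts.copy(),
        gene_symbols=symbols,
        is_mito=is_mito,
        is_ribo=is_ribo,
    )


def flag_genes(m: CountMatrix, include_mrp: bool = False) -> CountMatrix:
    """Set mito/ribo flags from existing symbols (or ids when symbols absent).

    Useful when the matrix already carries symbol-style names, as 10x
    ``features.tsv`` files and the synthetic fixtures do.
    """
    symbols = m.gene_symbols if m.gene_symbols is not None else m.gene_ids
    is_mito, is_ribo = flag_mito_ribo(symbols, include_mrp=include_mrp)
    out = CountMatrix(
        gene_ids=m.gene_ids.copy(),
        cell_ids=m.cell_ids.copy(),
        counts=m.counts.copy(),
        gene_symbols=None if m.gene_symbols is None else m.gene_symbols.copy(),
        is_mito=is_mito,
        is_ribo=is_ribo,
    )
    return out
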