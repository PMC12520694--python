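"""Readers and writers for every on-disk artifact the pipeline touches.

Count matrices travel as MatrixMarket coordinate triplets with 10x-style
``features.tsv`` / ``barcodes.tsv`` sidecars, or as dense delimited tables
(first column = cell id, header row = gene ids).  Gene sets use the standard
GMT format.  Annotations, labels and embeddings are header-bearing delimited
tables.  All writers emit UTF-8, tab-delimited text.

Validation is strict: duplicate identifiers, negative or fractional counts,
dimension mismatches and non-finite embedding values all raise
:class:`~hypoxclass.errors.ValidationError` rather than propagating silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "GeneAnnotation",
    "EmbeddingFile",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
    "read_embedding",
    "read_labels",
    "write_labels",
]


def _check_unique(ids: Sequence[str], axis: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {axis} ids: {dups[:10]}")


@dataclass
class CountMatrix:
    """Sparse cells x genes raw count matrix with identifiers.

    Counts are stored CSR, cells on the rows.  Entries must be
    non-negative integers (dtype may be float as long as values are
    integral, as MatrixMarket real-field exports sometimes are).
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: sp.csr_matrix
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"dimension mismatch: counts {self.counts.shape} vs "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        data = self.counts.data
        if data.size:
            if np.any(~np.isfinite(data)) or np.any(data < 0):
                raise ValidationError("negative or non-finite count entries")
            if np.any(data != np.round(data)):
                raise ValidationError("non-integral count entries")
        self.counts.data = self.counts.data.astype(np.float64)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class GeneSetCollection:
    """Named gene sets (ordered, duplicate-free within each set)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate genes within set {name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class GeneAnnotation:
    """Per-gene biotype and mitochondrial flags (one row per gene id)."""

    table: pd.DataFrame  # index gene_id, columns is_protein_coding, is_mitochondrial

    def __post_init__(self) -> None:
        required = {"is_protein_coding", "is_mitochondrial"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"annotation missing columns {required - set(self.table.columns)}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate gene ids in annotation")

    def lookup(self, gene_ids: Sequence[str], column: str) -> np.ndarray:
        """Boolean flags aligned to ``gene_ids``; missing genes default False.

        Missing annotation rows are treated as non-mitochondrial and
        non-coding, and the number of misses is logged.
        """
        reindexed = self.table[column].reindex(gene_ids)
        n_missing = int(reindexed.isna().sum())
        if n_missing:
            logger.warning("%d of %d genes lack annotation rows; treated as False for %s",
                           n_missing, len(gene_ids), column)
        return reindexed.fillna(False).to_numpy(dtype=bool)


@dataclass
class EmbeddingFile:
    """Dense cells x d embedding ingested from an external provider."""

    cell_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.cell_ids):
            raise ValidationError("embedding row count does not match cell ids")
        if self.matrix.shape[1] < 2:
            raise ValidationError("embedding must have at least 2 dimensions")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("non-finite value in embedding matrix")


# ---------------------------------------------------------------------------
# delimited-table helpers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    """Auto-detect comma vs tab from the header line."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_id_column(path: Path) -> list[str]:
    """First column of a headerless TSV (features/barcodes sidecar)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0].strip())
    return out


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, layout: str = "mtx_triplet", dataset_tag: str = "") -> CountMatrix:
    """Read a raw count matrix.

    Parameters
    ----------
    path
        For ``mtx_triplet``: a directory containing ``matrix.mtx``,
        ``features.tsv`` (gene ids) and ``barcodes.tsv`` (cell ids).
        For ``dense_table``: a delimited file, first column cell id,
        header row gene ids.
    layout
        ``"mtx_triplet"`` or ``"dense_table"``.

    Orientation of the MTX matrix is auto-detected from which axis length
    matches the barcodes table and normalized to cells x genes.
    """
    path = Path(path)
    if layout == "mtx_triplet":
        mtx = path / "matrix.mtx"
        feats = path / "features.tsv"
        bars = path / "barcodes.tsv"
        for p in (mtx, feats, bars):
            if not p.exists():
                raise ValidationError(f"missing file {p}")
        m = sp.coo_matrix(scipy.io.mmread(mtx))
        gene_ids = _read_id_column(feats)
        cell_ids = _read_id_column(bars)
        n_c, n_g = len(cell_ids), len(gene_ids)
        if m.shape == (n_g, n_c):
            # 10x convention: genes on rows (also covers the ambiguous
            # square case, resolved in favour of the 10x layout)
            m = m.T
        elif m.shape != (n_c, n_g):
            raise ValidationError(
                f"dimension mismatch: matrix {m.shape} vs {n_c} barcodes x {n_g} features"
            )
        return CountMatrix(cell_ids, gene_ids, m.tocsr(), dataset_tag)
    if layout == "dense_table":
        sep = _sniff_sep(path)
        df = pd.read_csv(path, sep=sep, index_col=0)
        return CountMatrix(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            sp.csr_matrix(df.to_numpy()),
            dataset_tag,
        )
    raise ValidationError(f"unknown counts layout {layout!r}")


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix as a 10x-style MatrixMarket triplet directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = cm.counts.T.tocoo()  # genes x cells, 10x convention
    mat = sp.coo_matrix((mat.data.astype(np.int64), (mat.row, mat.col)), shape=mat.shape)
    scipy.io.mmwrite(str(path / "matrix.mtx"), mat, field="integer")
    (path / "features.tsv").write_text("\n".join(cm.gene_ids) + "\n", encoding="utf-8")
    (path / "barcodes.tsv").write_text("\n".join(cm.cell_ids) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are dropped keeping the first
    occurrence; empty lines are skipped; gene ids are whitespace-trimmed
    and matched case-sensitively.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3 or not any(fields[2:]):
                raise ValidationError(f"no genes on line {lineno}")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"duplicate set name {name!r} on line {lineno}")
            genes: list[str] = []
            for g in fields[2:]:
                if g and g not in genes:
                    genes.append(g)
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# annotation, labels, embeddings
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a gene annotation table (gene_id, is_protein_coding, is_mitochondrial)."""
    sep = _sniff_sep(Path(path))
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in ("is_protein_coding", "is_mitochondrial"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="gene_id")


def read_embedding(path: str | Path, expected_cells: Sequence[str]) -> EmbeddingFile:
    """Read a dense cells x d embedding table and align rows to ``expected_cells``.

    Raises if any expected cell is absent (listing up to 10 missing ids)
    or if any value is non-finite.
    """
    sep = _sniff_sep(Path(path))
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    missing = [c for c in expected_cells if c not in df.index]
    if missing:
        shown = ", ".join(missing[:10])
        raise ValidationError(f"missing cells: {shown}")
    mat = df.loc[list(expected_cells)].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(mat)):
        raise ValidationError("non-finite value in embedding matrix")
    return EmbeddingFile(list(expected_cells), mat)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a label table written by :func:`write_labels`."""
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str})


def write_labels(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
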