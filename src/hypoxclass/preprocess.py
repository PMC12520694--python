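"""Cell/gene quality control and library-size log-normalization.

QC removes cells with fewer than ``min_genes_per_cell`` detected genes
(strict ``<``), cells whose mitochondrial count fraction exceeds
``max_mito_fraction`` (strict ``>``), and flagged doublets; genes detected
in fewer than ``min_cells_per_gene_fraction`` of the retained cells are
dropped as high-dropout genes.  Normalization is log1p counts-per-
scale-factor — downstream gene-set scoring is rank-based and mixture
labeling is affine-invariant, so this choice cannot change labels relative
to any monotone within-cell transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError
from .formats_io import CountMatrix, GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = ["QCParams", "QCReport", "NormalizedMatrix", "qc_filter", "log_normalize"]


@dataclass
class QCParams:
    min_genes_per_cell: int = 500
    max_mito_fraction: float = 0.20
    min_cells_per_gene_fraction: float = 0.001
    drop_doublets: bool = True

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValidationError("min_genes_per_cell must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    """Removal counts per rule; cell rules may overlap (a cell can fail several)."""

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    cells_low_genes: int
    cells_high_mito: int
    cells_doublet: int
    genes_high_dropout: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, same identifiers as the QC-passed counts."""

    cell_ids: list[str]
    gene_ids: list[str]
    values: sp.csr_matrix  # cells x genes, log1p CP-scale_factor
    scale_factor: float = 1e4

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=np.float64)


def qc_filter(
    counts: CountMatrix,
    ann: GeneAnnotation,
    params: QCParams | None = None,
    doublet_flags: np.ndarray | None = None,
) -> tuple[CountMatrix, QCReport]:
    """Apply cell- and gene-level QC, returning the filtered matrix and a report.

    Cell removal: detected genes < ``min_genes_per_cell`` OR mito count
    fraction > ``max_mito_fraction`` OR doublet flag set.  Gene removal:
    detected in fewer than ``min_cells_per_gene_fraction`` of retained cells.
    """
    params = params or QCParams()
    X = counts.counts
    n_cells, n_genes = X.shape

    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = ann.lookup(counts.gene_ids, "is_mitochondrial")
    if not mito_mask.any():
        # fallback when flags are absent entirely: MT- name prefix
        prefix = np.array([g.startswith("MT-") for g in counts.gene_ids])
        if prefix.any():
            logger.warning("no mitochondrial flags in annotation; using MT- prefix fallback")
            mito_mask = prefix
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros(n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)

    low_genes = detected < params.min_genes_per_cell
    high_mito = mito_frac > params.max_mito_fraction
    if doublet_flags is not None and params.drop_doublets:
        doublet = np.asarray(doublet_flags, dtype=bool)
        if doublet.shape != (n_cells,):
            raise ValidationError("doublet_flags length does not match cell count")
    else:
        doublet = np.zeros(n_cells, dtype=bool)

    keep_cells = ~(low_genes | high_mito | doublet)
    if not keep_cells.any():
        raise ValidationError("empty matrix after QC: no cells survive")

    Xc = X[keep_cells]
    n_retained = int(keep_cells.sum())
    gene_detect = np.asarray((Xc > 0).sum(axis=0)).ravel()
    keep_genes = gene_detect >= params.min_cells_per_gene_fraction * n_retained
    if not keep_genes.any():
        raise ValidationError("empty matrix after QC: no genes survive")

    out = CountMatrix(
        [c for c, k in zip(counts.cell_ids, keep_cells) if k],
        [g for g, k in zip(counts.gene_ids, keep_genes) if k],
        Xc[:, keep_genes].tocsr(),
        counts.dataset_tag,
    )
    report = QCReport(
        n_cells_in=n_cells,
        n_cells_out=out.n_cells,
        n_genes_in=n_genes,
        n_genes_out=out.n_genes,
        cells_low_genes=int(low_genes.sum()),
        cells_high_mito=int(high_mito.sum()),
        cells_doublet=int(doublet.sum()),
        genes_high_dropout=int((~keep_genes).sum()),
    )
    return out, report


def log_normalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """value(c, g) = ln(1 + count(c, g) * scale_factor / total(c))."""
    totals = np.asarray(counts.counts.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise ValidationError("cell with zero total count; run QC first")
    X = counts.counts.tocoo()
    data = np.log1p(X.data * scale_factor / totals[X.row])
    values = sp.csr_matrix((data, (X.row, X.col)), shape=X.shape)
    return NormalizedMatrix(list(counts.cell_ids), list(counts.gene_ids), values, scale_factor)
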