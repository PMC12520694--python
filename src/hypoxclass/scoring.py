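"""Per-cell single-sample gene-set enrichment (ssGSEA) scores.

For one cell, genes are ranked by expression (highest first) and the
enrichment score of a gene set G is the summed difference between the
weighted in-set cumulative distribution and the uniform out-of-set
cumulative distribution along that ranking:

    ES(G) = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{g in G, pos(g) <= i} r_g^alpha / sum_{g in G} r_g^alpha
    P_out(i) = |{g not in G : pos(g) <= i}| / (N - |G|)

with rank weight ``r_g = N - position + 1``.  Tied expression values
receive average rank weights, and the running-sum order among tied genes
is fixed by ascending gene id, so scores are fully deterministic on the
zero-inflated matrices typical of scRNA-seq.  Scores are rank-based:
any strictly increasing transform of a cell's expression leaves them
unchanged, so raw, CPM or log-normalized input give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError
from .formats_io import GeneSetCollection
from .preprocess import NormalizedMatrix

__all__ = ["ScoreMatrix", "ssgsea_score"]


@dataclass
class ScoreMatrix:
    """Dense cells x gene-sets enrichment scores."""

    cell_ids: list[str]
    set_names: list[str]
    scores: np.ndarray
    alpha: float
    coverage: dict[str, float]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.cell_ids), len(self.set_names)):
            raise ValidationError("score matrix shape inconsistent with ids")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("non-finite enrichment score")


def ssgsea_score(
    norm: NormalizedMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    min_genes_present: int = 3,
) -> ScoreMatrix:
    """Score every gene set in every cell.

    Parameters
    ----------
    norm
        Log-normalized expression (any monotone-equivalent scale works).
    sets
        Gene sets; each must retain at least ``min_genes_present`` genes
        after intersection with the matrix genes and must not cover the
        whole gene universe.
    alpha
        Rank-weight exponent (canonical ssGSEA value 0.25).
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    gene_ids = np.asarray(norm.gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)

    member_masks: dict[str, np.ndarray] = {}
    coverage: dict[str, float] = {}
    for name, genes in sets.sets.items():
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        coverage[name] = len(idx) / len(genes)
        if len(idx) < min_genes_present:
            raise ValidationError(
                f"gene set {name!r} retains {len(idx)} genes in the matrix "
                f"(< min_genes_present={min_genes_present})"
            )
        if len(idx) == n_genes:
            raise ValidationError(f"degenerate gene set {name!r}: covers every gene")
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        member_masks[name] = mask

    X = norm.values.tocsr()
    set_names = list(sets.sets)
    scores = np.empty((norm.n_cells, len(set_names)), dtype=np.float64)
    masks = np.stack([member_masks[n] for n in set_names])  # sets x genes

    for c in range(norm.n_cells):
        expr = np.asarray(X[c].todense()).ravel()
        # average rank weights: highest expression -> weight N
        weights = rankdata(expr, method="average")
        # running-sum order: descending expression, ties by ascending gene id
        order = np.lexsort((gene_ids, -expr))
        w_ord = weights[order] ** alpha
        for s in range(len(set_names)):
            m_ord = masks[s][order]
            w_in = np.where(m_ord, w_ord, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            n_out = n_genes - int(masks[s].sum())
            p_out = np.cumsum(~m_ord) / n_out
            scores[c, s] = float(np.sum(p_in - p_out))

    return ScoreMatrix(list(norm.cell_ids), set_names, scores, alpha, coverage)
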