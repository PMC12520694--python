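"""Hypoxia signature derivation by Wilcoxon rank-sum differential expression.

Genes are tested between the high-confidence hypoxic and normoxic groups
with the Mann-Whitney U (rank-sum) test; a gene enters the signature when
its raw two-sided p-value is below ``p_thresh``, its log2 fold change
exceeds ``lfc_thresh`` (hypoxic over normoxic, i.e. up in hypoxia only),
and it is protein-coding.  Benjamini-Hochberg adjusted p-values are
reported for transparency but deliberately NOT used in the filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, mannwhitneyu

from .errors import ValidationError
from .formats_io import GeneAnnotation
from .labeling import HC_HYPOXIC, HC_NORMOXIC, LabelTable
from .preprocess import NormalizedMatrix

__all__ = ["rank_sum_test", "derive_signature"]

_EXACT_N_MAX = 12


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two samples.

    Average ranks are used for ties.  The p-value is exact (full
    enumeration over label assignments) when the combined sample size is
    at most 12 and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction is used.  Returns
    ``(U statistic of x, two-sided p)``.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test requires non-empty groups")
    combined = np.concatenate([x, y])
    if np.unique(combined).size == 1:
        # every value tied: statistic at its null mean, no evidence
        return float(x.size * y.size / 2.0), 1.0
    no_ties = np.unique(combined).size == combined.size
    if combined.size <= _EXACT_N_MAX and no_ties:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def derive_signature(
    norm: NormalizedMatrix,
    labels: LabelTable,
    ann: GeneAnnotation,
    p_thresh: float = 0.05,
    lfc_thresh: float = 0.25,
    min_pct: float = 0.10,
) -> pd.DataFrame:
    """Derive the signature table from high-confidence groups.

    Genes are tested only when detected in at least ``min_pct`` of either
    group.  ``log2_fc = log2((m_h + 1) / (m_n + 1))`` where ``m`` is the
    group mean of ``expm1`` of the normalized value (mean de-logged
    expression).  The returned frame is sorted by descending log2_fc with
    columns gene_id, log2_fc, p_value, adj_p, pct_hypoxic, pct_normoxic,
    passes.
    """
    status = pd.Series(labels.status, index=labels.cell_ids)
    cells = pd.Index(norm.cell_ids)
    hyp_mask = status.reindex(cells).eq(HC_HYPOXIC).to_numpy()
    nor_mask = status.reindex(cells).eq(HC_NORMOXIC).to_numpy()
    if hyp_mask.sum() < 3 or nor_mask.sum() < 3:
        raise ValidationError(
            f"insufficient labeled cells: {int(hyp_mask.sum())} hypoxic, "
            f"{int(nor_mask.sum())} normoxic (need >= 3 each)"
        )

    X = norm.values.tocsc()
    Xh = np.asarray(X[hyp_mask].todense())
    Xn = np.asarray(X[nor_mask].todense())

    pct_h = (Xh > 0).mean(axis=0)
    pct_n = (Xn > 0).mean(axis=0)
    tested = (pct_h >= min_pct) | (pct_n >= min_pct)
    if not tested.any():
        raise ValidationError("no genes pass the detection filter")

    m_h = np.expm1(Xh[:, tested]).mean(axis=0)
    m_n = np.expm1(Xn[:, tested]).mean(axis=0)
    log2_fc = np.log2((m_h + 1.0) / (m_n + 1.0))

    res = mannwhitneyu(
        Xh[:, tested], Xn[:, tested], alternative="two-sided",
        method="asymptotic", use_continuity=True, axis=0,
    )
    pvals = np.minimum(np.asarray(res.pvalue, dtype=np.float64), 1.0)
    # constant genes give nan under the tie-corrected normal approximation
    constant = np.array([
        np.unique(np.concatenate([Xh[:, j], Xn[:, j]])).size == 1
        for j in np.flatnonzero(tested)
    ])
    pvals[constant] = 1.0
    adj_p = false_discovery_control(pvals, method="bh")

    gene_ids = np.asarray(norm.gene_ids)[tested]
    coding = ann.lookup(gene_ids, "is_protein_coding")
    passes = (pvals < p_thresh) & (log2_fc > lfc_thresh) & coding

    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2_fc": log2_fc,
            "p_value": pvals,
            "adj_p": adj_p,
            "pct_hypoxic": pct_h[tested],
            "pct_normoxic": pct_n[tested],
            "passes": passes,
        }
    ).sort_values("log2_fc", ascending=False, kind="mergesort", ignore_index=True)
    return table
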