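"""Feature matrices for classification: external embeddings, SVD fallback, raw signature.

The external-file provider ingests a dense cells x d matrix exported from a
pretrained single-cell foundation model; nothing of the model itself lives
here.  The ``svd_fallback`` provider is a deterministic truncated SVD of the
centered log-normalized matrix (restricted to signature genes, or to the
2000 most variable genes when no signature is supplied) so the full
pipeline and benchmark are runnable offline.  The ``raw_signature``
provider is the raw-count-style comparator: normalized expression of the
passing signature genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .formats_io import read_embedding
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = ["EmbeddingProviderSpec", "FeatureMatrix", "build_features"]

PROVIDER_KINDS = ("external_file", "svd_fallback", "raw_signature")


@dataclass
class EmbeddingProviderSpec:
    kind: str = "svd_fallback"
    dim: int = 50
    seed: int = 0
    source_path: Path | str | None = None

    def __post_init__(self) -> None:
        if self.kind not in PROVIDER_KINDS:
            raise ValidationError(f"unknown provider kind {self.kind!r}")
        if self.kind == "svd_fallback" and self.dim < 2:
            raise ValidationError("svd_fallback requires dim >= 2")
        if self.kind == "external_file" and self.source_path is None:
            raise ValidationError("external_file provider requires source_path")


@dataclass
class FeatureMatrix:
    cell_ids: list[str]
    values: np.ndarray
    feature_mode: str  # "embedding" or "raw_counts"
    provenance: object = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.cell_ids):
            raise ValidationError("feature rows do not match cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite feature value")

    def subset(self, cell_ids: list[str]) -> "FeatureMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise ValidationError(f"cells absent from feature matrix: {missing[:10]}")
        idx = [pos[c] for c in cell_ids]
        return FeatureMatrix(list(cell_ids), self.values[idx], self.feature_mode, self.provenance)


def _signature_gene_index(norm: NormalizedMatrix, signature: pd.DataFrame) -> np.ndarray:
    genes = signature.loc[signature["passes"], "gene_id"].tolist()
    if not genes:
        raise ValidationError("signature has no passing genes")
    pos = {g: i for i, g in enumerate(norm.gene_ids)}
    idx = [pos[g] for g in genes if g in pos]
    if not idx:
        raise ValidationError("no signature gene present in the matrix")
    return np.asarray(idx, dtype=int)


def _deterministic_svd(X: np.ndarray, dim: int) -> np.ndarray:
    """Truncated SVD of a centered matrix with a fixed sign convention.

    Columns are mean-centered; components are capped at the numerical
    rank; the sign of each component is fixed so that its largest-
    magnitude right-singular loading is positive, making the output
    invariant to row order.
    """
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(Xc.shape) * np.finfo(np.float64).eps if s.size else 0.0
    rank = int((s > tol).sum())
    k = min(dim, rank)
    if k < dim:
        logger.warning("requested dim %d exceeds matrix rank %d; capped", dim, rank)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for j in range(k):
        i_star = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_star] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    return u * s


def build_features(
    norm: NormalizedMatrix,
    spec: EmbeddingProviderSpec,
    signature: pd.DataFrame | None = None,
    n_top_genes: int = 2000,
) -> FeatureMatrix:
    """Build the cells x d feature matrix named by ``spec``."""
    if spec.kind == "external_file":
        emb = read_embedding(spec.source_path, norm.cell_ids)
        return FeatureMatrix(emb.cell_ids, emb.matrix, "embedding", spec)

    if spec.kind == "svd_fallback":
        if signature is not None:
            idx = _signature_gene_index(norm, signature)
        else:
            dense_var = _column_variances(norm)
            top = min(n_top_genes, dense_var.size)
            idx = np.sort(np.argsort(dense_var, kind="stable")[::-1][:top])
        X = np.asarray(norm.values.tocsc()[:, idx].todense(), dtype=np.float64)
        feats = _deterministic_svd(X, spec.dim)
        return FeatureMatrix(list(norm.cell_ids), feats, "embedding", spec)

    if spec.kind == "raw_signature":
        if signature is None:
            raise ValidationError("raw_signature provider requires a signature")
        idx = _signature_gene_index(norm, signature)
        X = np.asarray(norm.values.tocsc()[:, idx].todense(), dtype=np.float64)
        return FeatureMatrix(list(norm.cell_ids), X, "raw_counts", "signature")

    raise ValidationError(f"unknown provider kind {spec.kind!r}")


def _column_variances(norm: NormalizedMatrix) -> np.ndarray:
    X = norm.values.tocsc()
    mean = np.asarray(X.mean(axis=0)).ravel()
    mean_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    return mean_sq - mean**2
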