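"""Learning-curve benchmark across the classifier panel and final prediction.

A single stratified holdout (default 30%) is drawn once and reused as the
test set for every training fraction, so curves across fractions are
comparable.  For each fraction f in 0.1..1.0 a stratified sample of
floor(f * pool) cells is drawn from the remaining pool and every
(model x feature mode) pair is trained on it and scored — accuracy, AUROC
and F1 for the positive (hypoxic) class — on the holdout and on any extra
validation sets.  Models are ranked per metric by their mean metric over
evaluation conditions; the model with the smallest mean rank across the
three metrics is selected (ties broken by AUROC rank, then name), and the
intersection of the per-metric top-3 sets is reported alongside.

Gradient-boosting backends beyond scikit-learn (CatBoost, XGBoost,
LightGBM) are optional: if an import fails the model is skipped with a
logged warning, never a crash.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .embeddings import FeatureMatrix
from .errors import ValidationError
from .labeling import HC_HYPOXIC

logger = logging.getLogger(__name__)

__all__ = [
    "ALL_MODEL_NAMES",
    "BenchConfig",
    "Metrics",
    "BenchmarkReport",
    "available_models",
    "equal_interval_splits",
    "evaluate_scores",
    "rank_models",
    "rank_and_select",
    "run_benchmark",
    "classify_low_confidence",
]

ALL_MODEL_NAMES = [
    "logistic_regression",
    "gradient_boosted_trees",
    "categorical_boosting",
    "extreme_gradient_boosting",
    "light_gradient_boosting",
    "random_forest",
    "decision_tree",
    "naive_bayes",
    "linear_svm",
    "mlp",
]


def _make_model(name: str, seed: int):
    """Instantiate one classifier with library-default hyperparameters, seeded.

    Returns None (with a warning) when an optional backend is missing.
    """
    if name == "logistic_regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "gradient_boosted_trees":
        return GradientBoostingClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "linear_svm":
        # probability=True (Platt scaling) so every model exposes predict_proba;
        # CalibratedClassifierCV cannot fit the 1-per-class training sets the
        # smallest stratified fractions are allowed to produce
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            return SVC(kernel="linear", probability=True, random_state=seed)
    if name == "mlp":
        return MLPClassifier(random_state=seed, max_iter=500)
    if name == "categorical_boosting":
        try:
            from catboost import CatBoostClassifier
        except ImportError:
            return None
        return CatBoostClassifier(verbose=0, random_seed=seed, allow_writing_files=False)
    if name == "extreme_gradient_boosting":
        try:
            from xgboost import XGBClassifier
        except ImportError:
            return None
        return XGBClassifier(random_state=seed, eval_metric="logloss")
    if name == "light_gradient_boosting":
        try:
            from lightgbm import LGBMClassifier
        except ImportError:
            return None
        return LGBMClassifier(random_state=seed, verbose=-1)
    raise ValidationError(f"unknown model name {name!r}")


def available_models(names: list[str], seed: int = 0) -> dict[str, object]:
    """Resolve model names to estimators, skipping unavailable backends."""
    out = {}
    for name in names:
        model = _make_model(name, seed)
        if model is None:
            logger.warning("model backend for %r unavailable; skipped", name)
        else:
            out[name] = model
    if not out:
        raise ValidationError("no model backend available")
    return out


@dataclass
class BenchConfig:
    model_names: list[str] = field(default_factory=lambda: list(ALL_MODEL_NAMES))
    fractions: list[float] = field(default_factory=lambda: [round(0.1 * i, 1) for i in range(1, 11)])
    holdout_fraction: float = 0.3
    seed: int = 0
    positive_label: str = HC_HYPOXIC
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.model_names:
            raise ValidationError("model_names must be non-empty")
        if not all(0.0 < f <= 1.0 for f in self.fractions):
            raise ValidationError("fractions must lie in (0, 1]")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValidationError("holdout_fraction must lie in (0, 1)")


@dataclass
class Metrics:
    accuracy: float
    auroc: float | None
    f1: float


def _stratified_take(rng: np.random.Generator, idx_by_class: list[np.ndarray],
                     counts: list[int]) -> np.ndarray:
    parts = [rng.choice(idx, size=c, replace=False) for idx, c in zip(idx_by_class, counts)]
    return np.sort(np.concatenate(parts))


def equal_interval_splits(
    labels: np.ndarray, cfg: BenchConfig
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Stratified holdout plus equal-interval training fractions.

    One fixed stratified holdout of ``holdout_fraction`` is drawn once
    (seeded) and reused as the test set at every fraction.  For each
    fraction f the training set is an independent seeded stratified draw
    of floor(f * pool) cells from the remaining pool, with per-class
    counts floor-rounded and at least 1 per class.  Returns a list of
    ``(fraction, train_idx, test_idx)``.
    """
    y = np.asarray(labels).astype(bool)
    n = y.size
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if pos_idx.size < 10 or neg_idx.size < 10:
        raise ValidationError("need at least 10 cells per class to benchmark")

    rng = np.random.default_rng([int(cfg.seed), 0])
    hold_counts = [int(np.floor(cfg.holdout_fraction * pos_idx.size)),
                   int(np.floor(cfg.holdout_fraction * neg_idx.size))]
    hold_counts = [max(1, c) for c in hold_counts]
    test_idx = _stratified_take(rng, [pos_idx, neg_idx], hold_counts)
    test_mask = np.zeros(n, dtype=bool)
    test_mask[test_idx] = True
    pool_pos = pos_idx[~test_mask[pos_idx]]
    pool_neg = neg_idx[~test_mask[neg_idx]]

    splits = []
    for k, f in enumerate(cfg.fractions):
        frng = np.random.default_rng([int(cfg.seed), 1, k])
        counts = [max(1, int(np.floor(f * pool_pos.size))),
                  max(1, int(np.floor(f * pool_neg.size)))]
        train_idx = _stratified_take(frng, [pool_pos, pool_neg], counts)
        if train_idx.size < 2:
            raise ValidationError(f"fraction {f} yields fewer than 2 training cells")
        splits.append((f, train_idx, test_idx))
    return splits


def evaluate_scores(truth: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> Metrics:
    """Accuracy, AUROC and F1 of continuous positive-class scores.

    AUROC uses the rank (Mann-Whitney) formulation, crediting ties 0.5;
    when the truth contains a single class it is undefined and reported
    as None with a warning.  The hard label is ``score > threshold``
    (strict, so a score of exactly ``threshold`` is negative).
    """
    y = np.asarray(truth).astype(bool).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValidationError("truth and scores have different lengths")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        logger.warning("single-class truth: AUROC undefined")
        auroc = None
    else:
        ranks = rankdata(s, method="average")
        auroc = float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
    pred = s > threshold
    accuracy = float((pred == y).mean())
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    f1 = 0.0 if (2 * tp + fp + fn) == 0 else 2.0 * tp / (2 * tp + fp + fn)
    return Metrics(accuracy=accuracy, auroc=auroc, f1=float(f1))


def _positive_scores(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    pos_col = int(np.flatnonzero(np.asarray(model.classes_) == 1)[0])
    return proba[:, pos_col]


@dataclass
class BenchmarkReport:
    rows: pd.DataFrame                 # model, feature_mode, fraction, dataset_tag, metrics
    mean_ranks: pd.DataFrame           # model x metric mean ranks + overall
    top3_intersection: list[str]
    selected_model: str
    deltas: pd.DataFrame | None = None  # embedding-vs-raw paired metric differences
    final_model: object = None          # selected model retrained on the full pool
    config: BenchConfig | None = None


_METRICS = ["accuracy", "auroc", "f1"]


def rank_models(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-metric mean model ranks over evaluation conditions.

    Within every (fraction, dataset_tag) condition, models are ranked
    per metric (rank 1 = best, average ranks for ties); the ranks are
    then averaged over conditions, giving a model x metric table with a
    ``mean_rank`` column averaging the three metrics.
    """
    work = rows.copy()
    for m in _METRICS:
        work[m] = pd.to_numeric(work[m])
        work[f"rank_{m}"] = work.groupby(["fraction", "dataset_tag"])[m].rank(
            ascending=False, method="average"
        )
    ranks = work.groupby("model")[[f"rank_{m}" for m in _METRICS]].mean()
    ranks.columns = _METRICS
    ranks["mean_rank"] = ranks[_METRICS].mean(axis=1)
    return ranks


def rank_and_select(ranks: pd.DataFrame) -> tuple[list[str], str]:
    """Top-3 intersection and selected model from a model x metric rank table.

    Selection minimizes ``mean_rank``; ties break by AUROC rank, then
    lexicographic model name.  The top-3 intersection is the set of
    models in the best three of *every* metric, in ascending mean-rank
    order.
    """
    top3_sets = [set(ranks[m].nsmallest(3).index) for m in _METRICS]
    inter = set.intersection(*top3_sets)
    key = ranks.assign(name=ranks.index).sort_values(["mean_rank", "auroc", "name"])
    top3 = [m for m in key.index if m in inter]
    return top3, str(key.index[0])


def run_benchmark(
    features_by_mode: dict[str, FeatureMatrix],
    labels: np.ndarray,
    cfg: BenchConfig,
    extra_validation: list[tuple[FeatureMatrix, np.ndarray, str]] | None = None,
) -> BenchmarkReport:
    """Train the model panel across fractions and feature modes.

    ``labels`` is the per-cell binary truth (positive = hypoxic) aligned
    to every feature matrix in ``features_by_mode``.  Model selection is
    computed on the ``embedding`` feature mode when present, and the
    selected model is refit on the full pool of embedding features.
    """
    y = np.asarray(labels).astype(int).ravel()
    n = y.size
    for mode, fm in features_by_mode.items():
        if fm.values.shape[0] != n:
            raise ValidationError(f"feature mode {mode!r} not aligned to labels")
    models = available_models(cfg.model_names, cfg.seed)
    splits = equal_interval_splits(y, cfg)

    records = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        warnings.filterwarnings("ignore", category=FutureWarning)
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        for mode, fm in features_by_mode.items():
            X = fm.values
            for f, train_idx, test_idx in splits:
                for name in models:
                    model = _make_model(name, cfg.seed)
                    model.fit(X[train_idx], y[train_idx])
                    eval_sets = [("internal_holdout", X[test_idx], y[test_idx])]
                    for extra_fm, extra_y, tag in extra_validation or []:
                        eval_sets.append((tag, extra_fm.values, np.asarray(extra_y).astype(int)))
                    for tag, Xe, ye in eval_sets:
                        met = evaluate_scores(ye, _positive_scores(model, Xe), cfg.threshold)
                        records.append(
                            dict(model=name, feature_mode=mode, fraction=f, dataset_tag=tag,
                                 accuracy=met.accuracy, auroc=met.auroc, f1=met.f1)
                        )
    rows = pd.DataFrame.from_records(records)
    rows["auroc"] = pd.to_numeric(rows["auroc"])

    select_mode = "embedding" if "embedding" in features_by_mode else next(iter(features_by_mode))
    mean_ranks = rank_models(rows[rows.feature_mode == select_mode])
    top3, selected = rank_and_select(mean_ranks)

    deltas = None
    if {"embedding", "raw_counts"} <= set(features_by_mode):
        emb = rows[rows.feature_mode == "embedding"].set_index(["model", "fraction", "dataset_tag"])
        raw = rows[rows.feature_mode == "raw_counts"].set_index(["model", "fraction", "dataset_tag"])
        deltas = (emb[["accuracy", "auroc", "f1"]] - raw[["accuracy", "auroc", "f1"]]).reset_index()

    final = _make_model(selected, cfg.seed)
    pool_mask = np.ones(n, dtype=bool)
    pool_mask[splits[0][2]] = False  # exclude the holdout, as in training
    Xsel = features_by_mode[select_mode].values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(Xsel[pool_mask], y[pool_mask])

    return BenchmarkReport(rows, mean_ranks, top3, selected, deltas, final, cfg)


def classify_low_confidence(
    model, features: FeatureMatrix, threshold: float = 0.5
) -> pd.DataFrame:
    """Predict the hypoxia state of low-confidence cells.

    Returns a frame with cell_id, probability of the hypoxic class, and
    predicted status HYPOXIC / NORMOXIC (strict ``>`` on the threshold,
    so a probability of exactly 0.5 is NORMOXIC).
    """
    n_expected = getattr(model, "n_features_in_", None)
    if n_expected is not None and features.values.shape[1] != n_expected:
        raise ValidationError(
            f"feature dimensionality {features.values.shape[1]} does not match "
            f"the trained model ({n_expected})"
        )
    prob = _positive_scores(model, features.values)
    status = np.where(prob > threshold, "HYPOXIC", "NORMOXIC")
    return pd.DataFrame({"cell_id": features.cell_ids, "probability": prob, "predicted": status})
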