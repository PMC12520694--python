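import numpy as np
import pandas as pd
import pytest

import hypoxclass as hx
from hypoxclass.bench import rank_models, rank_and_select, available_models
from hypoxclass.errors import ValidationError

from _oracles import auroc_brute

FAST_MODELS = ["logistic_regression", "naive_bayes", "decision_tree"]


def _labels_100():
    return np.array([1] * 20 + [0] * 80)


class TestSplits:
    def test_arithmetic_example(self):
        cfg = hx.BenchConfig(model_names=FAST_MODELS, fractions=[0.5], seed=0)
        splits = hx.equal_interval_splits(_labels_100(), cfg)
        f, train, test = splits[0]
        y = _labels_100()
        assert test.size == 30 and y[test].sum() == 6
        assert train.size == 35 and y[train].sum() == 7
        assert not set(train) & set(test)

    def test_full_fraction_takes_entire_pool(self):
        cfg = hx.BenchConfig(model_names=FAST_MODELS, fractions=[1.0], seed=0)
        f, train, test = hx.equal_interval_splits(_labels_100(), cfg)[0]
        assert train.size == 70

    def test_determinism_and_stratification(self):
        y = _labels_100()
        cfg1 = hx.BenchConfig(model_names=FAST_MODELS, fractions=[0.5], seed=3)
        cfg2 = hx.BenchConfig(model_names=FAST_MODELS, fractions=[0.5], seed=4)
        a = hx.equal_interval_splits(y, cfg1)
        b = hx.equal_interval_splits(y, cfg1)
        c = hx.equal_interval_splits(y, cfg2)
        assert np.array_equal(a[0][1], b[0][1]) and np.array_equal(a[0][2], b[0][2])
        assert not np.array_equal(a[0][1], c[0][1])
        # class composition identical across seeds
        assert y[a[0][1]].sum() == y[c[0][1]].sum()

    def test_too_few_per_class_errors(self):
        y = np.array([1] * 5 + [0] * 50)
        with pytest.raises(ValidationError, match="at least 10"):
            hx.equal_interval_splits(y, hx.BenchConfig(model_names=FAST_MODELS))


class TestEvaluateScores:
    def test_worked_example(self):
        m = hx.evaluate_scores(np.array([1, 0, 1, 0]), np.array([0.9, 0.8, 0.4, 0.2]))
        assert m.auroc == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(0.5)
        assert m.f1 == pytest.approx(0.5)

    def test_perfect_separation(self):
        m = hx.evaluate_scores(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.2, 0.1]))
        assert (m.accuracy, m.auroc, m.f1) == (1.0, 1.0, 1.0)

    def test_all_tied_scores(self):
        m = hx.evaluate_scores(np.array([1, 0, 1, 0]), np.full(4, 0.7))
        assert m.auroc == pytest.approx(0.5)

    def test_single_class_truth(self, caplog):
        m = hx.evaluate_scores(np.ones(4), np.array([0.9, 0.8, 0.4, 0.2]))
        assert m.auroc is None
        assert 0.0 <= m.accuracy <= 1.0

    def test_matches_pairwise_enumeration(self, rng):
        for n in (5, 23, 100, 200):
            y = rng.random(n) < 0.3
            if y.all() or not y.any():
                continue
            s = rng.choice(np.linspace(0, 1, 7), size=n)  # ties likely
            m = hx.evaluate_scores(y, s)
            assert m.auroc == pytest.approx(auroc_brute(y, s), abs=1e-12)

    def test_permutation_invariance(self, rng):
        y = np.array([1, 1, 0, 0, 1, 0, 0, 0])
        s = rng.random(8)
        m1 = hx.evaluate_scores(y, s)
        perm = rng.permutation(8)
        m2 = hx.evaluate_scores(y[perm], s[perm])
        assert (m1.accuracy, m1.auroc, m1.f1) == (m2.accuracy, m2.auroc, m2.f1)


class TestRankSelection:
    def test_worked_three_model_table(self):
        rows = pd.DataFrame([
            dict(model="A", feature_mode="embedding", fraction=1.0, dataset_tag="internal",
                 accuracy=0.9, auroc=0.8, f1=0.9),
            dict(model="B", feature_mode="embedding", fraction=1.0, dataset_tag="internal",
                 accuracy=0.8, auroc=0.9, f1=0.8),
            dict(model="C", feature_mode="embedding", fraction=1.0, dataset_tag="internal",
                 accuracy=0.7, auroc=0.7, f1=0.7),
        ])
        ranks = rank_models(rows)
        assert ranks.loc["A", "mean_rank"] == pytest.approx(4 / 3)
        assert ranks.loc["B", "mean_rank"] == pytest.approx(5 / 3)
        assert ranks.loc["C", "mean_rank"] == pytest.approx(3.0)
        top3, selected = rank_and_select(ranks)
        assert selected == "A"
        assert set(top3) == {"A", "B", "C"}

    def test_single_model_degenerate(self):
        rows = pd.DataFrame([dict(model="only", feature_mode="embedding", fraction=0.5,
                                  dataset_tag="internal", accuracy=0.8, auroc=0.8, f1=0.8)])
        ranks = rank_models(rows)
        assert (ranks.loc["only", ["accuracy", "auroc", "f1"]] == 1.0).all()
        top3, selected = rank_and_select(ranks)
        assert selected == "only" and top3 == ["only"]


@pytest.fixture(scope="module")
def tiny_features(request):
    rng = np.random.default_rng(11)
    n = 120
    y = np.array([1] * 30 + [0] * 90)
    centers = np.where(y[:, None], 2.0, 0.0)
    emb = hx.FeatureMatrix([f"c{i}" for i in range(n)],
                           centers + rng.normal(size=(n, 4)), "embedding")
    raw = hx.FeatureMatrix([f"c{i}" for i in range(n)],
                           centers + rng.normal(size=(n, 4)), "raw_counts")
    return {"embedding": emb, "raw_counts": raw}, y


class TestRunBenchmark:
    def test_report_completeness_and_selection(self, tiny_features):
        feats, y = tiny_features
        cfg = hx.BenchConfig(model_names=FAST_MODELS, fractions=[0.5, 1.0], seed=0)
        report = hx.run_benchmark(feats, y, cfg)
        # rows = models x modes x fractions x evaluation sets
        assert len(report.rows) == len(FAST_MODELS) * 2 * 2 * 1
        assert report.selected_model in FAST_MODELS
        assert set(report.top3_intersection) <= set(FAST_MODELS)
        assert report.deltas is not None and len(report.deltas) == len(FAST_MODELS) * 2
        assert report.final_model is not None

    def test_extra_validation_sets(self, tiny_features, rng):
        feats, y = tiny_features
        extra_y = np.array([1] * 10 + [0] * 20)
        extra = hx.FeatureMatrix([f"v{i}" for i in range(30)],
                                 np.where(extra_y[:, None], 2.0, 0.0) + rng.normal(size=(30, 4)),
                                 "embedding")
        cfg = hx.BenchConfig(model_names=["logistic_regression"], fractions=[1.0], seed=0)
        report = hx.run_benchmark(feats, y, cfg, extra_validation=[(extra, extra_y, "cell_line_1")])
        assert set(report.rows.dataset_tag) == {"internal_holdout", "cell_line_1"}
        assert len(report.rows) == 1 * 2 * 1 * 2

    def test_unavailable_backend_skipped(self, caplog):
        import builtins
        real_import = builtins.__import__

        def refuse_boosters(name, *args, **kwargs):
            if name in ("catboost", "xgboost", "lightgbm"):
                raise ImportError(name)
            return real_import(name, *args, **kwargs)

        builtins.__import__ = refuse_boosters
        try:
            models = available_models(["categorical_boosting", "logistic_regression"])
        finally:
            builtins.__import__ = real_import
        assert list(models) == ["logistic_regression"]

    def test_learning_curve_sanity(self):
        # mean holdout AUROC at f=1.0 >= at f=0.1, averaged over 5 seeds
        deltas = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 300
            y = (rng.random(n) < 0.3).astype(int)
            if y.sum() < 10 or (1 - y).sum() < 10:
                continue
            X = np.where(y[:, None], 1.0, 0.0) + rng.normal(scale=2.0, size=(n, 5))
            feats = {"embedding": hx.FeatureMatrix([f"c{i}" for i in range(n)], X, "embedding")}
            cfg = hx.BenchConfig(model_names=["logistic_regression"],
                                 fractions=[0.1, 1.0], seed=seed)
            rows = hx.run_benchmark(feats, y, cfg).rows
            lo = rows[rows.fraction == 0.1].auroc.mean()
            hi = rows[rows.fraction == 1.0].auroc.mean()
            deltas.append(hi - lo)
        assert np.mean(deltas) >= 0.0


class TestClassifyLowConfidence:
    def _trained(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(2, 1, size=(50, 3)), rng.normal(-2, 1, size=(50, 3))])
        y = np.array([1] * 50 + [0] * 50)
        from sklearn.linear_model import LogisticRegression
        return LogisticRegression().fit(X, y)

    def test_threshold_rule(self):
        model = self._trained()
        fm = hx.FeatureMatrix(["hi", "lo"], np.array([[5.0, 5, 5], [-5.0, -5, -5]]), "embedding")
        out = hx.classify_low_confidence(model, fm)
        assert out.set_index("cell_id").predicted.to_dict() == {"hi": "HYPOXIC", "lo": "NORMOXIC"}

    def test_probability_exactly_half_is_normoxic(self):
        model = self._trained()

        class Half:
            classes_ = np.array([0, 1])
            n_features_in_ = 3

            def predict_proba(self, X):
                return np.full((len(X), 2), 0.5)

        fm = hx.FeatureMatrix(["c"], np.zeros((1, 3)), "embedding")
        out = hx.classify_low_confidence(Half(), fm)
        assert out.predicted.iloc[0] == "NORMOXIC"

    def test_dim_mismatch_errors(self):
        model = self._trained()
        fm = hx.FeatureMatrix(["c"], np.zeros((1, 7)), "embedding")
        with pytest.raises(ValidationError, match="dimensionality"):
            hx.classify_low_confidence(model, fm)


def test_intermediates_near_hypoxic_archetype_predicted_hypoxic():
    """Planted intermediate cells with mixing weight 0.8 sit close to the
    hypoxic archetype; the trained classifier calls >= 80% of them HYPOXIC."""
    cm, truth, gsc, ann = hx.simulate(hx.SimParams(
        n_cells=600, n_genes=800, set_size=30, intermediate_mixing=0.8, seed=7))
    filtered, _ = hx.qc_filter(cm, ann)
    norm = hx.log_normalize(filtered)
    scores = hx.ssgsea_score(norm, gsc)
    labels, _ = hx.label_cells(scores, seed=7)
    sig = hx.derive_signature(norm, labels, ann)
    emb = hx.build_features(norm, hx.EmbeddingProviderSpec(kind="svd_fallback", dim=50), sig)
    hc = np.isin(labels.status, ["HC_HYPOXIC", "HC_NORMOXIC"])
    hc_ids = [c for c, m in zip(labels.cell_ids, hc) if m]
    y = (labels.status[hc] == "HC_HYPOXIC").astype(int)
    cfg = hx.BenchConfig(model_names=FAST_MODELS, fractions=[1.0], seed=7)
    report = hx.run_benchmark({"embedding": emb.subset(hc_ids)}, y, cfg)
    inter = [c for c, s in zip(truth.table.cell_id, truth.states) if s == "INTERMEDIATE"]
    preds = hx.classify_low_confidence(report.final_model, emb.subset(inter))
    assert (preds.predicted == "HYPOXIC").mean() >= 0.80
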