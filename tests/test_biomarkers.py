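import numpy as np
import pytest
from scipy import stats as sps

from ptemark.biomarkers import (
    FeaturePanel,
    bca_ci,
    confusion_metrics,
    cross_validated_auc,
    evaluate_panel,
    fit_logistic,
    loo_pooled_scores,
    predict_proba,
    roc_auc,
)


def brute_force_auc(scores, labels):
    """Pairwise oracle: (#{pos>neg} + 0.5 ties) / (n_pos * n_neg)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_small_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(200):
            n1 = int(rng.integers(1, 13))
            n0 = int(rng.integers(1, 13))
            # integer scores force ties
            scores = rng.integers(0, 5, size=n0 + n1).astype(float)
            labels = np.array([0] * n0 + [1] * n1)
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_antisymmetry_without_ties(self, rng):
        scores = rng.normal(size=40)
        labels = np.array([0] * 20 + [1] * 20)
        assert roc_auc(-scores, labels) == pytest.approx(
            1.0 - roc_auc(scores, labels), abs=1e-12
        )

    def test_null_auc_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = np.array([0] * 1000 + [1] * 1000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.04)


class TestFitLogistic:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((4, 1)), np.ones(4))

    def test_separating_feature_monotone_probabilities(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        w = fit_logistic(X, y, ridge=1e-6)
        p = predict_proba(w, X)
        assert np.all(np.diff(p) > 0)

    def test_parameter_recovery(self, rng):
        n = 500
        X = rng.normal(size=(n, 2))
        eta = 1.0 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.random(n) < sps.logistic.cdf(eta)).astype(int)
        w = fit_logistic(X, y)
        assert w[1] == pytest.approx(1.0, abs=0.15)
        assert w[2] == pytest.approx(-0.5, abs=0.15)

    def test_agrees_with_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        n = 200
        X = rng.normal(size=(n, 3))
        y = (rng.random(n) < sps.logistic.cdf(X[:, 0])).astype(int)
        ridge = 1.0
        w = fit_logistic(X, y, ridge=ridge)
        clf = sklearn.LogisticRegression(
            C=1.0 / ridge, solver="lbfgs", tol=1e-10, max_iter=1000
        ).fit(X, y)
        assert w[0] == pytest.approx(clf.intercept_[0], abs=1e-4)
        assert np.allclose(w[1:], clf.coef_[0], atol=1e-4)


class TestLooPooledScores:
    def test_fold_structure_minimum_n(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        s = loo_pooled_scores(X, y)
        assert s.shape == (4,)
        assert not np.isnan(s).any()

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            loo_pooled_scores(np.zeros((3, 1)), np.array([0, 1, 0]))

    def test_duplicated_rows_identical_scores(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        X2 = np.vstack([X, X[3]])
        y2 = np.append(y, y[3])
        s = loo_pooled_scores(X2, y2)
        assert s[3] == pytest.approx(s[10], abs=1e-9)

    def test_fold_losing_a_class_flagged_missing(self):
        X = np.arange(6, dtype=float).reshape(-1, 1)
        y = np.array([1, 0, 0, 0, 0, 0])
        s = loo_pooled_scores(X, y)
        assert np.isnan(s[0])  # removing the only positive leaves one class
        assert not np.isnan(s[1:]).any()


class TestCrossValidatedAuc:
    def test_perfectly_separating_scores(self, rng):
        X = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(10, 0.1, 10)])[:, None]
        y = np.array([0] * 10 + [1] * 10)
        cv, (lo, hi) = cross_validated_auc(X, y, B=300, seed=0)
        assert cv == 1.0
        assert hi == 1.0

    def test_binormal_apparent_auc(self, rng):
        # two-group Gaussian shift delta=1: AUC = Phi(1/sqrt(2)) ~ 0.760
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(1, 1, 200)])
        y = np.array([0] * 200 + [1] * 200)
        assert roc_auc(x, y) == pytest.approx(sps.norm.cdf(1 / np.sqrt(2)), abs=0.03)

    def test_score_negation_antisymmetry(self, rng):
        s = rng.normal(size=30)
        y = np.array([0, 1] * 15)
        assert roc_auc(-s, y) == pytest.approx(1 - roc_auc(s, y))


class TestBcaCi:
    def test_zero_variance_degenerate_point(self):
        lo, hi = bca_ci(np.mean, np.ones(20), B=300, seed=0)
        assert lo == hi == 1.0

    def test_close_to_percentile_for_symmetric_statistic(self, rng):
        data = rng.normal(size=50)
        lo, hi = bca_ci(np.mean, data, B=2000, seed=1)
        boot = np.array([
            np.mean(rng.choice(data, size=50)) for _ in range(2000)
        ])
        plo, phi = np.quantile(boot, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=0.1)
        assert hi == pytest.approx(phi, abs=0.1)

    def test_agrees_with_scipy_bca(self, rng):
        data = rng.exponential(size=40)
        lo, hi = bca_ci(np.mean, data, B=4000, seed=2)
        res = sps.bootstrap(
            (data,), np.mean, n_resamples=4000, method="BCa",
            random_state=np.random.default_rng(3), confidence_level=0.95,
        )
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.08)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.08)

    def test_b_minimum_enforced(self):
        with pytest.raises(ValueError):
            bca_ci(np.mean, np.ones(5), B=50)


class TestConfusionMetrics:
    def test_perfect_scores(self):
        mis, sens, spec, prec = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert (mis, sens, spec, prec) == (0.0, 1.0, 1.0, 1.0)

    def test_all_predicted_negative(self):
        mis, sens, spec, prec = confusion_metrics([0.1, 0.2, 0.3, 0.4], [1, 0, 1, 0])
        assert sens == 0.0
        assert spec == 1.0
        assert prec is None

    def test_hand_counts(self):
        scores = [0.9] * 11 + [0.1] * 4 + [0.1] * 5 + [0.9] * 2
        labels = [1] * 11 + [1] * 4 + [0] * 5 + [0] * 2
        mis, sens, spec, prec = confusion_metrics(scores, labels)
        assert mis == pytest.approx(6 / 22)
        assert sens == pytest.approx(11 / 15)
        assert spec == pytest.approx(5 / 7)
        assert prec == pytest.approx(11 / 13)


class TestEvaluatePanel:
    def _panel(self, rng, n=30, shift=2.0):
        X = np.vstack([
            rng.normal(0, 1, size=(n, 3)),
            rng.normal(shift, 1, size=(n, 3)),
        ])
        y = np.array([0] * n + [1] * n)
        return FeaturePanel(
            feature_names=("f1", "f2", "f3"), X=X, y=y, contrast_name="test"
        )

    def test_strong_effect_high_cv_auc(self, rng):
        ev = evaluate_panel(self._panel(rng), seed=1, B=300)
        assert ev.cv_auc > 0.7
        assert ev.cv_ci[0] <= ev.cv_auc <= ev.cv_ci[1]
        assert 0 <= ev.misclassification_rate <= 1

    def test_deterministic_under_seed(self, rng):
        panel = self._panel(rng)
        e1 = evaluate_panel(panel, seed=7, B=300)
        e2 = evaluate_panel(panel, seed=7, B=300)
        assert e1 == e2

    def test_listwise_deletion_and_class_minimum(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "animal_id": list("abcdef"),
                "f1": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0],
                "y": [0, 0, 0, 1, 1, 1],
            }
        )
        panel = FeaturePanel.from_frame(df, ["f1"], "y")
        assert len(panel.y) == 5
        df.loc[3:5, "f1"] = np.nan
        with pytest.raises(ValueError, match="fewer than 2"):
            FeaturePanel.from_frame(df, ["f1"], "y")

    def test_missing_feature_named(self):
        import pandas as pd

        df = pd.DataFrame({"animal_id": ["a"], "y": [1]})
        with pytest.raises(KeyError, match="nope"):
            FeaturePanel.from_frame(df, ["nope"], "y")
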