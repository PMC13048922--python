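"""Stepwise selection behaviour, metrics, thresholding and the bootstrap
protocol, each checked against simple independent constructions."""

import numpy as np
import pandas as pd
import pytest

import phenocube as pc
from phenocube.classifiers import _bic, _intercept_only


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _logistic_data(n, betas, n_noise, seed, intercept=0.0):
    """Features ~ N(0,1); labels from a known logistic model on the first
    len(betas) columns."""
    rng = np.random.default_rng(seed)
    p = len(betas) + n_noise
    X = rng.normal(size=(n, p))
    lin = intercept + X[:, :len(betas)] @ np.asarray(betas)
    y = (rng.random(n) < _sigmoid(lin)).astype(int)
    cols = [f"x{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestStepwiseLogistic:
    def test_intercept_only_on_balanced_labels(self):
        X = pd.DataFrame({"a": np.zeros(40)})
        y = np.r_[np.ones(20), np.zeros(20)]
        with pytest.warns(UserWarning, match="constant"):
            model = pc.stepwise_logistic(X, y)
        assert model.selected_features == []
        assert model.intercept == pytest.approx(0.0)

    def test_true_driver_selected_first(self):
        X, y = _logistic_data(400, [2.5], n_noise=23, seed=0)
        model = pc.stepwise_logistic(X, y)
        assert model.selected_features[0] == "x0"
        assert model.coefficients["x0"] > 0

    def test_null_prefers_intercept_only(self):
        """With a handful of independent noise candidates and n large enough
        for the BIC penalty to bite, selection nearly always stops at the
        intercept."""
        kept = 0
        n_rep = 40
        for s in range(n_rep):
            X, y = _logistic_data(1000, [], n_noise=4, seed=100 + s)
            model = pc.stepwise_logistic(X, y)
            kept += model.selected_features == []
        assert kept / n_rep >= 0.9

    def test_selected_bic_never_above_intercept_bic(self):
        X, y = _logistic_data(300, [1.5, -1.0], n_noise=10, seed=1)
        model = pc.stepwise_logistic(X, y)
        traj = model.fit_metadata["bic_trajectory"]
        assert traj[-1]["bic"] <= traj[0]["bic"]
        _, llf0 = _intercept_only(y)
        assert traj[0]["bic"] == pytest.approx(_bic(llf0, 1, len(y)))

    def test_duplicated_feature_never_enters(self):
        X, y = _logistic_data(500, [3.0], n_noise=3, seed=2)
        X["x0_copy"] = X["x0"]
        model = pc.stepwise_logistic(X, y)
        assert "x0" in model.selected_features
        assert "x0_copy" not in model.selected_features

    def test_perfect_separation_flagged_and_finite(self):
        X = pd.DataFrame({"a": np.r_[np.linspace(-2, -1, 20), np.linspace(1, 2, 20)]})
        y = np.r_[np.zeros(20), np.ones(20)]
        model = pc.stepwise_logistic(X, y)
        assert model.fit_metadata["ridge_fallback"]
        assert np.isfinite(model.coefficients["a"])
        assert (model.predict(X) >= 0.5).astype(int).tolist() == y.tolist()

    def test_support_and_sign_recovery(self):
        """Strong known drivers are recovered with correct signs in nearly
        every seeded replicate (small-scale version of the full check)."""
        betas = [3.0, -3.0, 2.5, -2.5]
        ok = 0
        n_rep = 20
        for s in range(n_rep):
            X, y = _logistic_data(1000, betas, n_noise=20, seed=200 + s)
            m = pc.stepwise_logistic(X, y)
            sel = set(m.selected_features)
            good = {f"x{i}" for i in range(4)} <= sel
            good = good and all(np.sign(m.coefficients[f"x{i}"]) == np.sign(b)
                                for i, b in enumerate(betas))
            ok += good
        assert ok / n_rep >= 0.95

    def test_model_json_round_trip(self):
        X, y = _logistic_data(300, [2.0], n_noise=2, seed=3)
        model = pc.stepwise_logistic(X, y)
        back = pc.LogisticModel.from_json(model.to_json())
        assert back.intercept == model.intercept
        assert back.coefficients == model.coefficients
        assert np.allclose(back.predict(X), model.predict(X))


class TestNeuralNet:
    def test_separable_toy_reaches_full_training_accuracy(self):
        X = pd.DataFrame({"a": np.r_[np.linspace(-2, -1, 30), np.linspace(1, 2, 30)],
                          "b": np.zeros(60)})
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        net = pc.fit_neural_net(X, y, seed=0)
        assert np.mean((net.predict(X) >= 0.5) == y) == 1.0

    def test_seeded_refit_is_identical(self):
        X, y = _logistic_data(200, [1.0], n_noise=3, seed=4)
        n1 = pc.fit_neural_net(X, y, seed=7)
        n2 = pc.fit_neural_net(X, y, seed=7)
        assert np.array_equal(n1.predict(X), n2.predict(X))

    def test_xor_structure_beats_logistic(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.uniform(-1, 1, size=(400, 2)), columns=["a", "b"])
        y = ((X["a"] * X["b"]) > 0).astype(int).to_numpy()
        net = pc.fit_neural_net(X, y, seed=1)
        nn_acc = np.mean((net.predict(X) >= 0.5) == y)
        lr = pc.stepwise_logistic(X, y)
        lr_acc = np.mean((lr.predict(X) >= 0.5) == y)
        assert nn_acc > 0.9
        assert lr_acc <= 0.6


class TestMetrics:
    def test_confusion_hand_case(self):
        pred = [1] * 9 + [0] * 1 + [0] * 8 + [1] * 2
        truth = [1] * 10 + [0] * 10
        m = pc.confusion_metrics(pred, truth)
        assert (m.sensitivity, m.specificity, m.accuracy) == (0.9, 0.8, 0.85)

    def test_all_correct(self):
        m = pc.confusion_metrics([1, 0, 1], [1, 0, 1])
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)

    def test_undefined_metric_is_none_not_zero(self):
        m = pc.confusion_metrics([0, 0], [0, 0])
        assert m.sensitivity is None and m.specificity == 1.0

    def test_auc_perfect_tied_and_hand_cases(self):
        assert pc.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert pc.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5
        # pos {0.9, 0.4}, neg {0.5, 0.1}: 3 concordant of 4 pairs
        assert pc.roc_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_auc_matches_pairwise_oracle_and_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.round(rng.random(20), 2), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            brute = np.mean((pos[:, None] > neg[None, :])
                            + 0.5 * (pos[:, None] == neg[None, :]))
            got = pc.roc_auc(scores, labels)
            assert got == pytest.approx(brute, abs=1e-12)
            assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError):
            pc.roc_auc([0.1, 0.9], [1, 1])


class TestSelectThreshold:
    def test_separated_scores_pick_cut_nearest_half(self):
        t = pc.select_threshold([0.3, 0.3, 0.7, 0.7], [0, 0, 1, 1])
        assert t == 0.7

    def test_degenerate_scores_return_half_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            assert pc.select_threshold([0.4] * 4, [0, 1, 0, 1]) == 0.5

    def test_symmetric_overlap_near_half(self):
        rng = np.random.default_rng(7)
        n = 4000
        scores = np.r_[rng.normal(0.4, 0.1, n), rng.normal(0.6, 0.1, n)]
        labels = np.r_[np.zeros(n), np.ones(n)]
        t = pc.select_threshold(scores, labels)
        assert abs(t - 0.5) < 0.05


class _ColumnScorer:
    """'Fitted model' that scores by reading one feature column."""

    def __init__(self, col):
        self.col = col

    def predict(self, X):
        return X[self.col].to_numpy(dtype=float)


class TestBootstrapEvaluate:
    def test_perfect_scorer(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=120)
        X = pd.DataFrame({"truth": y.astype(float)})
        rep = pc.bootstrap_evaluate(lambda Xt, yt: _ColumnScorer("truth"), X, y,
                                    n_boot=10, seed=0)
        for role in ("training", "validation"):
            for metric, (mean, se) in rep.metrics[role].items():
                assert mean == 1.0 and se == 0.0

    def test_coin_flip_scorer_auc_near_half(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, size=3000)
        X = pd.DataFrame({"noise": rng.random(3000)})
        rep = pc.bootstrap_evaluate(lambda Xt, yt: _ColumnScorer("noise"), X, y,
                                    n_boot=10, seed=1)
        auc_mean, _ = rep.metrics["validation"]["auc"]
        assert abs(auc_mean - 0.5) < 0.05

    def test_same_seed_identical_report(self):
        X, y = _logistic_data(200, [2.0], n_noise=3, seed=10)
        fitter = lambda Xt, yt: pc.stepwise_logistic(Xt, yt)
        r1 = pc.bootstrap_evaluate(fitter, X, y, n_boot=5, seed=3)
        r2 = pc.bootstrap_evaluate(fitter, X, y, n_boot=5, seed=3)
        assert r1.per_boot.equals(r2.per_boot)

    def test_split_fraction_respected(self):
        X, y = _logistic_data(300, [2.0], n_noise=1, seed=11)
        captured = []
        def fitter(Xt, yt):
            captured.append(len(yt))
            return _ColumnScorer("x0")
        pc.bootstrap_evaluate(fitter, X, y, n_boot=2, seed=0)
        assert all(n == 200 for n in captured)

    def test_requires_two_bootstraps(self):
        X, y = _logistic_data(100, [1.0], n_noise=1, seed=12)
        with pytest.raises(ValueError):
            pc.bootstrap_evaluate(lambda a, b: _ColumnScorer("x0"), X, y, n_boot=1)
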