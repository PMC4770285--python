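"""Rank statistics, ROC, logistic and discriminant models."""

import math

import numpy as np
import pandas as pd
import pytest

import cleavstat as cs
from cleavstat.classify import predict_proba


class TestMannWhitney:
    def test_full_enumeration_separated(self):
        u, p = cs.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # exact two-sided p for 3 vs 3, U = 0

    def test_minimal_groups(self):
        u, _ = cs.mann_whitney([1], [2])
        assert u == 0

    def test_midranks_for_ties(self):
        u, p = cs.mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == 4.5 and p == 1.0

    def test_all_identical(self):
        u, p = cs.mann_whitney([2, 2], [2, 2, 2])
        assert p == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            cs.mann_whitney([], [1])


class TestRoc:
    def test_perfect_prediction(self):
        assert cs.roc([1, 2], [3, 4]).auc == 1.0

    def test_no_predictive_power(self):
        rng = np.random.default_rng(0)
        curve = cs.roc(rng.normal(size=5000), rng.normal(size=5000))
        assert curve.auc == pytest.approx(0.5, abs=0.03)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        curve = cs.roc(rng.normal(size=40), rng.normal(0.5, size=40))
        assert tuple(curve.points[0]) == (1.0, 1.0)
        assert tuple(curve.points[-1]) == (0.0, 0.0)
        assert np.all(np.diff(curve.points[:, 0]) <= 0)
        assert np.all(np.diff(curve.points[:, 1]) <= 0)

    def test_inverted_rule_orientation(self):
        curve = cs.roc([3, 4], [1, 2])
        assert curve.auc == 0.0
        assert curve.orientation == "below_diagonal"
        assert curve.efficacy == 1.0

    def test_auc_equals_mann_whitney_pair_fraction(self):
        """Rank identity: AUC == (#pos>neg + 0.5 #ties) / (n_pos * n_neg)."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            n_neg, n_pos = rng.integers(2, 40, size=2)
            neg = rng.integers(0, 12, size=n_neg).astype(float)  # force ties
            pos = rng.integers(0, 12, size=n_pos) + rng.uniform(0, 0.5, size=n_pos)
            pairs = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert cs.roc(neg, pos).auc == pytest.approx(pairs / (n_neg * n_pos),
                                                         abs=1e-12)


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        m = cs.fit_logistic(np.zeros((40, 0)), [0] * 20 + [1] * 20)
        assert m.intercept == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_unbalanced_closed_form(self):
        m = cs.fit_logistic(np.zeros((100, 0)), [0] * 30 + [1] * 70)
        assert m.intercept == pytest.approx(math.log(70 / 30), abs=1e-8)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            cs.fit_logistic(np.zeros((10, 1)), [1] * 10)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(10)
        b0, b1 = -0.5, 2.0
        x = rng.normal(size=5000)
        p = 1 / (1 + np.exp(-(b0 + b1 * x)))
        y = (rng.random(5000) < p).astype(int)
        m = cs.fit_logistic(pd.DataFrame({"x": x}), y)
        se0 = abs(m.intercept - b0)
        assert abs(m.intercept - b0) < 0.15 and abs(m.coefficients["x"] - b1) < 0.25

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(11)
        x = rng.normal(size=(300, 2))
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.3 + x[:, 0] - 0.7 * x[:, 1])))).astype(int)
        m = cs.fit_logistic(pd.DataFrame(x, columns=["a", "b"]), y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert m.intercept == pytest.approx(ref.params[0], abs=1e-5)
        assert m.coefficients["a"] == pytest.approx(ref.params[1], abs=1e-5)
        assert m.coefficients["b"] == pytest.approx(ref.params[2], abs=1e-5)
        # Wald chi-square = z^2
        assert m.wald["a"] == pytest.approx(ref.tvalues[1] ** 2, rel=1e-3)

    def test_complete_separation_capped_and_flagged(self):
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        y = [0] * 20 + [1] * 20
        with pytest.warns(UserWarning, match="separation"):
            m = cs.fit_logistic(pd.DataFrame({"x": x}), y)
        assert m.separation
        assert abs(m.coefficients["x"]) <= 30.0

    def test_log_likelihood_nondecreasing_over_irls(self):
        from cleavstat.classify import _irls, _log_likelihood
        rng = np.random.default_rng(12)
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        y = (rng.random(200) < 0.4).astype(float)
        lls = []
        beta = np.zeros(2)
        from scipy.special import expit
        for _ in range(8):
            p = expit(X @ beta)
            H = X.T @ (X * (p * (1 - p))[:, None]) + 1e-10 * np.eye(2)
            beta = beta + np.linalg.solve(H, X.T @ (y - p))
            lls.append(_log_likelihood(y, X @ beta))
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


class TestNagelkerke:
    def test_zero_for_intercept_only(self):
        y = [0] * 25 + [1] * 25
        m = cs.fit_logistic(np.zeros((50, 0)), y)
        assert cs.nagelkerke_r2(m, np.zeros((50, 0)), y) == pytest.approx(0.0, abs=1e-9)

    def test_approaches_one_under_separation(self):
        x = np.concatenate([np.full(30, -1.0), np.full(30, 1.0)])
        y = [0] * 30 + [1] * 30
        with pytest.warns(UserWarning):
            m = cs.fit_logistic(pd.DataFrame({"x": x}), y)
        assert cs.nagelkerke_r2(m, pd.DataFrame({"x": x}), y) > 0.99

    def test_hand_computed_four_points(self):
        # model b0=0, b1=1 on x=[-1,-1,1,1], y=[0,1,0,1]
        m = cs.BinaryLogisticModel(intercept=0.0, coefficients={"x": 1.0},
                                   included_rules=["x"])
        X = pd.DataFrame({"x": [-1.0, -1.0, 1.0, 1.0]})
        y = [0, 1, 0, 1]
        p = 1 / (1 + np.exp(-np.array([-1.0, -1.0, 1.0, 1.0])))
        ll1 = (np.log(1 - p[0]) + np.log(p[1]) + np.log(1 - p[2]) + np.log(p[3]))
        ll0 = 4 * math.log(0.5)
        r2_cs = 1 - math.exp((2 / 4) * (ll0 - ll1))
        expected = r2_cs / (1 - math.exp((2 / 4) * ll0))
        got = cs.nagelkerke_r2(m, X, y)
        assert got == pytest.approx(max(expected, 0.0), abs=1e-12)


class TestPredictBinary:
    def test_half_probability_at_zero_score(self):
        m = cs.BinaryLogisticModel(0.0, {}, [])
        p, decision = cs.predict_binary(m, {})
        assert p == 0.5 and not decision  # decision requires p > threshold

    def test_saturating_score(self):
        m = cs.BinaryLogisticModel(50.0, {}, [])
        p, decision = cs.predict_binary(m, {})
        assert p > 0.999999 and decision

    def test_direct_evaluation(self):
        m = cs.BinaryLogisticModel(0.0, {"r": 1.0}, ["r"])
        p, decision = cs.predict_binary(m, {"r": 0.2})
        assert p == pytest.approx(1 / (1 + math.exp(-0.2)), abs=1e-9)
        assert decision

    def test_missing_feature_raises(self):
        m = cs.BinaryLogisticModel(0.0, {"r": 1.0}, ["r"])
        with pytest.raises(KeyError):
            cs.predict_binary(m, {"other": 1.0})

    def test_json_round_trip(self):
        m = cs.BinaryLogisticModel(0.3, {"KR": -1.2, "AFILMV": 2.0},
                                   ["AFILMV", "KR"], p_threshold=0.4)
        m2 = cs.BinaryLogisticModel.from_json(m.to_json())
        assert m2.intercept == m.intercept
        assert m2.coefficients == m.coefficients
        assert m2.included_rules == m.included_rules
        assert m2.p_threshold == m.p_threshold


class TestStepwiseLogistic:
    @staticmethod
    def _informative_plus_noise(seed, n=1000):
        rng = np.random.default_rng(seed)
        info = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2.0 * info))).astype(int)
        noise = rng.normal(size=n)
        return pd.DataFrame({"noise": noise, "info": info}), y

    def test_informative_entered_first(self):
        wins = 0
        for seed in range(100):
            X, y = self._informative_plus_noise(seed, n=400)
            model, _ = cs.stepwise_logistic(X, y)
            if model.included_rules and model.included_rules[0] == "info":
                wins += 1
        assert wins >= 95

    def test_training_auc_nondecreasing(self):
        X, y = self._informative_plus_noise(3)
        X["info2"] = X["info"] + np.random.default_rng(4).normal(0, 0.5, len(X))
        _, curves = cs.stepwise_logistic(X, y)
        aucs = [c.auc for c in curves]
        assert aucs == sorted(aucs)

    def test_duplicate_predictor_not_entered(self):
        X, y = self._informative_plus_noise(5)
        X = X[["info"]].copy()
        X["info_copy"] = X["info"]
        model, _ = cs.stepwise_logistic(X, y)
        assert model.included_rules == ["info"]

    def test_all_noise_screen_survivor_rate(self):
        """Under the null, about alpha of predictors survive the screen."""
        rng = np.random.default_rng(6)
        survived = total = 0
        for _ in range(40):
            X = pd.DataFrame(rng.normal(size=(120, 10)),
                             columns=[f"r{i}" for i in range(10)])
            y = rng.integers(0, 2, size=120)
            for col in X.columns:
                _, p = cs.mann_whitney(X[col][y == 0], X[col][y == 1])
                survived += p < 0.05
                total += 1
        assert survived / total == pytest.approx(0.05, abs=0.02)

    def test_zero_survivors_intercept_only(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60)})
        y = [0] * 30 + [1] * 30
        with pytest.warns(UserWarning, match="screen"):
            model, curves = cs.stepwise_logistic(X, y, alpha_screen=1e-6)
        assert model.included_rules == [] and curves == []


class TestSplitStratified:
    def test_seventy_thirty(self):
        labels = {f"a{i}": "A" for i in range(100)}
        labels.update({f"b{i}": "B" for i in range(100)})
        plan = cs.split_stratified(labels, fraction=0.7, seed=1)
        train_a = sum(1 for i in plan.train if i.startswith("a"))
        test_a = sum(1 for i in plan.test if i.startswith("a"))
        assert (train_a, test_a) == (70, 30)
        assert len(plan.train) == 140 and len(plan.test) == 60
        assert set(plan.train) | set(plan.test) == set(labels)
        assert not set(plan.train) & set(plan.test)

    def test_determinism(self):
        labels = {f"x{i}": i % 2 for i in range(40)}
        a = cs.split_stratified(labels, seed=9)
        b = cs.split_stratified(labels, seed=9)
        assert a == b

    def test_full_train_boundary(self):
        labels = {"a": 0, "b": 0, "c": 1, "d": 1}
        with pytest.warns(UserWarning, match="empty test"):
            plan = cs.split_stratified(labels, fraction=1.0, seed=0)
        assert set(plan.train) == set(labels) and plan.test == ()

    def test_singleton_label_goes_to_train(self):
        labels = {"a": 0, "b": 0, "c": 1}
        with pytest.warns(UserWarning, match="single member"):
            plan = cs.split_stratified(labels, fraction=0.5, seed=0)
        assert "c" in plan.train


def _gaussian_classes(rng, means, n=60, k=3):
    rows, labels = [], []
    for c, mu in enumerate(means):
        rows.append(rng.normal(loc=mu, scale=1.0, size=(n, k)))
        labels += [f"c{c}"] * n
    return pd.DataFrame(np.vstack(rows), columns=[f"p{i}" for i in range(k)]), labels


class TestStepwiseLda:
    def test_separating_predictor_entered_first(self):
        rng = np.random.default_rng(21)
        # classes differ only along predictor p0
        X, y = _gaussian_classes(rng, [(0, 0, 0), (4, 0, 0), (8, 0, 0)])
        model = cs.stepwise_lda(X, y)
        assert model.included_predictors[0] == "p0"

    def test_identical_means_chance_accuracy(self):
        rng = np.random.default_rng(22)
        X, y = _gaussian_classes(rng, [(0, 0, 0)] * 3, n=80)
        model = cs.stepwise_lda(X, y, max_predictors=2)
        correct = sum(cs.classify_lda(model, row) == lab
                      for (_, row), lab in zip(X.iterrows(), y))
        assert correct / len(y) == pytest.approx(1 / 3, abs=0.12)

    def test_two_class_direction_agrees_with_logistic(self):
        rng = np.random.default_rng(23)
        X, y = _gaussian_classes(rng, [(0,), (5,)], n=80, k=1)
        lda = cs.stepwise_lda(X, y, max_predictors=1)
        logit = cs.fit_logistic(X, y)
        agree = 0
        for (_, row), lab in zip(X.iterrows(), y):
            lda_label = cs.classify_lda(lda, row)
            _, positive = cs.predict_binary(logit, row)
            logit_label = "c1" if positive else "c0"
            agree += lda_label == logit_label
        assert agree / len(y) > 0.95

    def test_two_rows_per_class_required(self):
        X = pd.DataFrame({"p0": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            cs.stepwise_lda(X, ["a", "a", "b"])


class TestClassifyLda:
    @staticmethod
    def _model():
        return cs.DiscriminantModel(
            classes=["a", "b"],
            means={"a": np.array([0.0]), "b": np.array([4.0])},
            pooled_cov=np.array([[1.0]]),
            included_predictors=["p0"],
        )

    def test_class_mean_assigned_to_its_class(self):
        m = self._model()
        assert cs.classify_lda(m, {"p0": 0.0}) == "a"
        assert cs.classify_lda(m, {"p0": 4.0}) == "b"

    def test_equidistant_tie_breaks_to_first_label(self):
        assert cs.classify_lda(self._model(), {"p0": 2.0}) == "a"

    def test_missing_feature_raises(self):
        with pytest.raises(KeyError):
            cs.classify_lda(self._model(), {"q": 1.0})

    def test_held_out_synthetic_recovery(self):
        rng = np.random.default_rng(24)
        X, y = _gaussian_classes(rng, [(0, 0), (5, 0), (0, 5)], n=60, k=2)
        model = cs.stepwise_lda(X, y)
        Xt, yt = _gaussian_classes(rng, [(0, 0), (5, 0), (0, 5)], n=40, k=2)
        correct = sum(cs.classify_lda(model, row) == lab
                      for (_, row), lab in zip(Xt.iterrows(), yt))
        assert correct / len(yt) >= 0.9
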