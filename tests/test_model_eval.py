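"""Ridge fitting, metrics, CIs, paired tests, and decision curves."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fistulomics.model_eval import (
    EvalReport,
    FittedRidge,
    RidgeConfig,
    auc_ci,
    delong_variance,
    evaluate,
    fit_ridge,
    net_benefit_curve,
    paired_model_test,
    repeated_evaluation,
)


class _ScoreModel:
    """Stand-in model emitting fixed probabilities (for metric tests)."""

    def __init__(self, probs):
        self._p = np.asarray(probs, float)

    def predict_proba(self, X):
        return self._p


def brute_force_auc(scores, labels):
    """Concordant-pair counting with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestFitRidge:
    def test_separable_data_perfect_training_auc(self, rng):
        y = np.repeat([0, 1], 30)
        X = np.column_stack([y * 4.0 + rng.normal(scale=0.1, size=60),
                             rng.normal(size=60)])
        model = fit_ridge(X, y, RidgeConfig(), seed=0)
        assert evaluate(model, X, y)["AUC"] == pytest.approx(1.0)

    def test_null_features_near_chance(self, rng):
        n = 300
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 10))
        train, test = np.arange(0, n, 2), np.arange(1, n, 2)
        model = fit_ridge(X[train], y[train], RidgeConfig(), seed=0)
        auc = evaluate(model, X[test], y[test])["AUC"]
        assert abs(auc - 0.5) <= 0.08

    def test_shrinkage_with_growing_penalty(self, rng):
        from sklearn.linear_model import LogisticRegression

        y = np.repeat([0, 1], 25)
        X = np.column_stack([y + rng.normal(scale=0.5, size=50),
                             rng.normal(size=50)])
        norms = []
        for alpha in (0.01, 1.0, 100.0, 10000.0):
            est = LogisticRegression(C=1.0 / alpha, penalty="l2", max_iter=1000)
            est.fit(X, y)
            norms.append(np.linalg.norm(est.coef_))
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_ridge(np.zeros((10, 2)), np.ones(10), RidgeConfig(), seed=0)

    def test_regression_mode_scores(self, rng):
        y = np.repeat([0, 1], 25)
        X = np.column_stack([y + rng.normal(scale=0.3, size=50)])
        model = fit_ridge(X, y, RidgeConfig(mode="regression"), seed=0)
        p = model.predict_proba(X)
        assert ((p >= 0) & (p <= 1)).all()
        assert evaluate(model, X, y)["AUC"] > 0.9


class TestEvaluate:
    def test_perfect_and_reversed_scores(self):
        y = [1, 1, 0, 0]
        perfect = evaluate(_ScoreModel([0.9, 0.8, 0.2, 0.1]), None, y)
        assert perfect["AUC"] == 1.0 and perfect["F1"] == 1.0
        reversed_ = evaluate(_ScoreModel([0.1, 0.2, 0.8, 0.9]), None, y)
        assert reversed_["AUC"] == 0.0

    def test_six_sample_hand_case(self):
        scores = [0.9, 0.8, 0.7, 0.4, 0.3, 0.2]
        labels = [1, 1, 0, 1, 0, 0]
        out = evaluate(_ScoreModel(scores), None, labels)
        assert out["AUC"] == pytest.approx(8.0 / 9.0)

    def test_auc_equals_brute_force_pair_counting(self, rng):
        for _ in range(5):
            n = int(rng.integers(20, 200))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            got = evaluate(_ScoreModel(s), None, y)["AUC"]
            assert got == pytest.approx(brute_force_auc(s, y), rel=1e-12)

    def test_single_class_cohort_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate(_ScoreModel([0.5, 0.5]), None, [1, 1])


class TestRepeatedEvaluation:
    def test_fixed_seed_reproducible(self, rng):
        n = 80
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        X["a"] += y
        r1 = repeated_evaluation(X, y, n_iter=3, seed=7)
        r2 = repeated_evaluation(X, y, n_iter=3, seed=7)
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_single_iteration_flags_undefined_std(self, rng):
        n = 60
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        rep = repeated_evaluation(X, y, n_iter=1, seed=0)
        agg = rep.aggregate()
        assert agg["std"].isna().all()
        assert agg["ci_lower"].isna().all()

    def test_aggregate_invariants(self, rng):
        n = 90
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        X["a"] += 0.8 * y
        rep = repeated_evaluation(X, y, n_iter=4, seed=1)
        agg = rep.aggregate()
        assert ((agg["mean"] >= 0) & (agg["mean"] <= 1)).all()
        assert (agg["std"].dropna() >= 0).all()
        ok = agg.dropna(subset=["ci_lower"])
        assert (ok["ci_lower"] <= ok["mean"] + 1e-12).all()
        assert (ok["mean"] <= ok["ci_upper"] + 1e-12).all()

    def test_stratified_split_preserves_class_counts(self, rng):
        from sklearn.model_selection import train_test_split

        y = rng.integers(0, 2, 101)
        idx_train, idx_test = train_test_split(
            np.arange(101), train_size=0.7, stratify=y, random_state=0
        )
        assert len(set(idx_train) & set(idx_test)) == 0
        assert len(idx_train) + len(idx_test) == 101
        for cls in (0, 1):
            frac = (y[idx_train] == cls).sum() / (y == cls).sum()
            assert abs(frac - 0.7) <= 1.0 / (y == cls).sum() + 1e-9


class TestAucCI:
    def test_perfect_separation_upper_bound_clipped(self):
        y = [0, 0, 1, 1, 1]
        s = [0.1, 0.2, 0.8, 0.9, 0.95]
        lo, hi = auc_ci(s, y, method="delong")
        assert hi == 1.0

    def test_delong_matches_placement_value_oracle(self, rng):
        """Variance equals the direct two-sample placement computation."""
        n = 60
        y = rng.integers(0, 2, n)
        s = rng.normal(size=n)
        auc, var = delong_variance(s, y)
        pos, neg = s[y == 1], s[y == 0]
        v10 = [(sum(p > q for q in neg) + 0.5 * sum(p == q for q in neg)) / len(neg)
               for p in pos]
        v01 = [(sum(p > q for p in pos) + 0.5 * sum(p == q for p in pos)) / len(pos)
               for q in neg]
        assert auc == pytest.approx(np.mean(v10), rel=1e-12)
        expected = np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)
        assert var == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_ci_covers_point_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        hits = 0
        for k in range(10):
            y = rng.integers(0, 2, 80)
            if len(np.unique(y)) < 2:
                y[0] = 1 - y[0]
            s = rng.normal(size=80) + 0.5 * y
            point = roc_auc_score(y, s)
            lo, hi = auc_ci(s, y, method="bootstrap", n_boot=300, seed=k)
            hits += lo <= point <= hi
        assert hits == 10


class TestPairedModelTest:
    def test_identical_vectors_tie_convention(self):
        with pytest.warns(UserWarning, match="tie"):
            assert paired_model_test([0.7, 0.8, 0.75], [0.7, 0.8, 0.75]) == 1.0

    def test_constant_shift_highly_significant(self, rng):
        a = 0.8 + 0.001 * rng.normal(size=30)
        b = a - 0.05
        assert paired_model_test(a, b) < 1e-3

    def test_t_statistic_matches_hand_formula(self):
        from scipy import stats

        a = np.array([0.71, 0.74, 0.69, 0.73, 0.70])
        b = np.array([0.70, 0.70, 0.68, 0.69, 0.71])
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_expected = 2 * stats.t.sf(abs(t), len(d) - 1)
        assert paired_model_test(a, b) == pytest.approx(p_expected, rel=1e-12)


class TestNetBenefit:
    def test_treat_all_limit_is_prevalence(self):
        y = [1, 1, 0, 0, 0]
        curve = net_benefit_curve([0.5] * 5, y, thresholds=[0.001])
        assert curve.treat_all[0] == pytest.approx(0.4, abs=1e-3)
        assert curve.treat_none[0] == 0.0

    def test_perfect_classifier_plateau(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        p = np.where(y == 1, 0.9, 0.05)
        curve = net_benefit_curve(p, y, thresholds=np.linspace(0.1, 0.8, 8))
        np.testing.assert_allclose(curve.net_benefit, 0.3, atol=1e-12)

    def test_hand_computed_net_benefit(self):
        """n=10, threshold 0.25, TP=3, FP=2: NB = 0.3 - 0.2/3."""
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        p = [0.9, 0.8, 0.3, 0.1, 0.6, 0.4, 0.2, 0.1, 0.05, 0.0]
        curve = net_benefit_curve(p, y, thresholds=[0.25])
        assert curve.net_benefit[0] == pytest.approx(0.3 - 0.2 * (0.25 / 0.75))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            net_benefit_curve([1.5], [1], thresholds=[0.5])
        with pytest.raises(ValueError, match="thresholds"):
            net_benefit_curve([0.5], [1], thresholds=[1.0])

    def test_reference_curves_depend_only_on_prevalence(self, rng):
        y = rng.integers(0, 2, 50)
        t = np.linspace(0.05, 0.9, 10)
        c1 = net_benefit_curve(rng.random(50), y, t)
        c2 = net_benefit_curve(rng.random(50), y, t)
        np.testing.assert_allclose(c1.treat_all, c2.treat_all)
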