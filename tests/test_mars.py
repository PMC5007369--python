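"""MARS forward/backward passes, importance, ROC and validation schemes."""

import numpy as np
import pandas as pd
import pytest

from snoquant.errors import ValidationError
from snoquant.mars import (
    MARS,
    mars_backward,
    mars_forward,
    roc_auc,
    validate,
    variable_importance,
)


def auc_oracle(scores, labels):
    """O(n^2) pairwise concordance with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return wins / (len(pos) * len(neg))


class TestForward:
    def test_noise_free_hinge_recovery(self):
        x = np.linspace(0.0, 1.0, 21)  # includes 0.5 exactly
        y = 2.0 * np.maximum(0.0, x - 0.5)
        bases, trace = mars_forward(x[:, None], y, max_bases=4)
        knots = {k for b in bases for _, k, _ in b.factors}
        assert 0.5 in knots
        assert trace[-1] < 1e-18  # training RSS -> 0

    def test_constant_y_gives_intercept_only(self):
        X = np.random.default_rng(0).uniform(0, 1, (20, 3))
        bases, trace = mars_forward(X, np.full(20, 7.0), max_bases=5)
        assert len(bases) == 1 and bases[0].is_intercept
        assert trace[-1] < 1e-20

    def test_only_informative_variable_used(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (120, 10))
        y = 3.0 * np.maximum(0, X[:, 1] - 0.4) - 2.0 * np.maximum(0, 0.4 - X[:, 1])
        bases, _ = mars_forward(X, y, max_bases=6)
        used = {v for b in bases for v in b.variables}
        assert used == {1}

    def test_rss_strictly_decreases(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (60, 4))
        y = np.sin(3 * X[:, 0]) + rng.normal(0, 0.1, 60)
        _, trace = mars_forward(X, y, max_bases=8)
        assert all(b < a for a, b in zip(trace, trace[1:]))

    def test_respects_max_bases(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (80, 5))
        y = rng.normal(0, 1, 80)
        bases, _ = mars_forward(X, y, max_bases=3)
        assert len(bases) - 1 <= 3

    def test_rejects_missing_values(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValidationError):
            mars_forward(X, np.array([1.0, 2.0]), max_bases=2)


class TestBackward:
    def test_pure_noise_prunes_to_near_empty(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (60, 5))
        y = rng.normal(0, 1, 60)
        fwd, _ = mars_forward(X, y, max_bases=12)
        bases, coef, gcv, trace = mars_backward(fwd, X, y)
        assert len(bases) - 1 <= 2

    def test_noise_free_signal_retained(self):
        x = np.linspace(0, 1, 41)
        y = 2.0 * np.maximum(0.0, x - 0.5)
        fwd, _ = mars_forward(x[:, None], y, max_bases=6)
        bases, coef, _, _ = mars_backward(fwd, x[:, None], y)
        pred = np.column_stack([b.evaluate(x[:, None]) for b in bases]) @ coef
        np.testing.assert_allclose(pred, y, atol=1e-10)

    def test_final_gcv_minimises_deletion_sequence(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (50, 3))
        y = np.maximum(0, X[:, 0] - 0.3) + rng.normal(0, 0.2, 50)
        fwd, _ = mars_forward(X, y, max_bases=10)
        _, _, gcv, trace = mars_backward(fwd, X, y)
        assert gcv <= min(g for _, g in trace) + 1e-15


class TestImportance:
    def test_single_variable_model(self):
        x = np.linspace(0, 1, 30)
        X = np.column_stack([x, np.random.default_rng(6).uniform(0, 1, 30)])
        y = np.maximum(0, x - 0.5)
        res = MARS(X, y).fit()
        assert res.importance.iloc[0] == 100.0
        assert res.importance.iloc[1] == 0.0

    def test_equal_effects_score_similarly(self):
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(30):
            X = rng.uniform(0, 1, (100, 2))
            y = X[:, 0] + X[:, 1] + rng.normal(0, 0.05, 100)
            res = MARS(X, y, max_bases=8).fit()
            diffs.append(abs(res.importance.iloc[0] - res.importance.iloc[1]))
        assert np.mean(diffs) < 20.0

    def test_null_features_score_zero_after_pruning(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, (60, 4))
        y = rng.normal(0, 1, 60)
        res = MARS(X, y).fit()
        if res.n_hinge_terms == 0:
            assert (res.importance == 0).all()


class TestAdditivity:
    def test_degree_one_predictions_are_additive(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, (80, 3))
        y = np.maximum(0, X[:, 0] - 0.5) + X[:, 1] ** 2 + rng.normal(0, 0.05, 80)
        res = MARS(X, y, max_interaction=1).fit()
        probe = rng.uniform(0, 1, (10, 3))
        a, b = probe.copy(), probe.copy()
        a[:, 0], b[:, 0] = 0.2, 0.8
        delta = res.predict(b) - res.predict(a)
        # effect of moving x0 is constant regardless of other features
        np.testing.assert_allclose(delta, delta[0], atol=1e-10)


class TestKnotRecovery:
    def brute_force_first_knot(self, x, y):
        """Exhaustive RSS-optimal reflected-pair knot (the greedy-step oracle)."""
        best = None
        for k in np.unique(x):
            B = np.column_stack(
                [np.ones(len(x)), np.maximum(0, x - k), np.maximum(0, k - x)]
            )
            coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
            r = y - B @ coef
            rss = float(r @ r)
            if best is None or rss < best[0]:
                best = (rss, k)
        return best[1]

    def test_first_knot_matches_exhaustive_oracle(self):
        k_star = 0.37
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = rng.uniform(0, 1, 200)
            y = np.maximum(0, x - k_star) + rng.normal(0, 0.01, 200)
            bases, _ = mars_forward(x[:, None], y, max_bases=2)
            first_knot = bases[1].factors[0][1]
            assert first_knot == pytest.approx(self.brute_force_first_knot(x, y))

    def test_knot_concentrates_around_true_break(self):
        # noise sigma = 0.01 at n = 200: the RSS-optimal knot lands within a
        # few data spacings of the true break in every seeded run
        k_star = 0.37
        dists = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            x = rng.uniform(0, 1, 200)
            y = np.maximum(0, x - k_star) + rng.normal(0, 0.01, 200)
            res = MARS(x[:, None], y, max_bases=4).fit()
            knots = [k for b in res.bases for _, k, _ in b.factors]
            assert knots, "signal pruned away"
            dists.append(min(abs(k - k_star) for k in knots))
        dists = np.array(dists)
        assert (dists <= 0.03).all()
        # and most runs land within the data values bracketing the break
        assert (dists <= 0.011).mean() >= 0.8


class TestRocAuc:
    def test_worked_example(self):
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_perfect_ordering(self):
        _, auc = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_all_ties(self):
        _, auc = roc_auc([5.0] * 8, [0, 1] * 4)
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(10)
        for n in (5, 20, 200):
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]  # both classes present
            scores = np.round(rng.normal(0, 1, n), 1)  # coarse -> ties occur
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(0, 1, 40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        points, _ = roc_auc(scores, labels)
        assert (points["fpr"].diff().dropna() >= 0).all()
        assert (points["tpr"].diff().dropna() >= 0).all()
        assert points.iloc[-1]["fpr"] == 1.0 and points.iloc[-1]["tpr"] == 1.0


def two_class_data(rng, n_per_class=30, n_features=6, shift=4.0):
    X = rng.normal(0, 1, (2 * n_per_class, n_features))
    X[n_per_class:, 0] += shift
    y = np.r_[np.zeros(n_per_class), np.ones(n_per_class)]
    return pd.DataFrame(X), y


class TestValidation:
    def test_separable_training_auc_is_one(self):
        X, y = two_class_data(np.random.default_rng(13))
        for scheme in ("cv10", "split80_20"):
            v = validate(X, y, scheme, seed=0)
            assert v.auc_train == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(14)
        X, y = two_class_data(rng, n_per_class=30)
        y_perm = rng.permutation(y)
        v = validate(X, y_perm, "cv10", seed=0)
        assert abs(v.auc_test - 0.5) < 0.2

    def test_reproducible_given_seed(self):
        X, y = two_class_data(np.random.default_rng(15))
        v1 = validate(X, y, "split80_20", seed=3)
        v2 = validate(X, y, "split80_20", seed=3)
        np.testing.assert_array_equal(v1.scores_test, v2.scores_test)
        assert v1.auc_test == v2.auc_test

    def test_unknown_scheme_rejected(self):
        X, y = two_class_data(np.random.default_rng(16))
        with pytest.raises(ValidationError):
            validate(X, y, "loocv", seed=0)

    def test_too_few_samples_for_cv(self):
        X, y = two_class_data(np.random.default_rng(17), n_per_class=3)
        with pytest.raises(ValidationError):
            validate(X, y, "cv10", seed=0)


class TestResultsSurface:
    def test_summary_and_json_round_trip(self, tmp_path):
        X, y = two_class_data(np.random.default_rng(18), n_per_class=15)
        res = MARS(X, y).fit()
        text = res.summary()
        assert "GCV" in text and "(intercept)" in text
        path = tmp_path / "model.json"
        res.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["coefficients"][0] == pytest.approx(res.params[0])
        assert len(payload["bases"]) == len(res.bases)

    def test_importance_threshold_selection(self):
        X, y = two_class_data(np.random.default_rng(19))
        res = MARS(X, y).fit()
        assert res.selected_variables(min_importance=20.0) == ["0"]
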