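"""From-scratch GBDT, GOSS sampling, EFB bundling and the histogram booster."""

import numpy as np
import pytest

from herbscreen.boosting import (GBDTModel, GossConfig, apply_bundles,
                                 efb_bundle, fit_gbdt, fit_goss_gbm,
                                 goss_sample, predict_score,
                                 reconstruct_from_bundles)


@pytest.fixture
def toy(rng):
    X = np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(4, 0.5, (10, 2))])
    y = np.concatenate([np.zeros(10), np.ones(10)])
    return X, y


class TestFitGbdt:
    def test_zero_trees_returns_prior(self, toy):
        X, y = toy
        m = fit_gbdt(X, y, M=0)
        prior = 1 / (1 + np.exp(-np.log(y.mean() / (1 - y.mean()))))
        assert np.allclose(m.predict_score(X), prior)

    def test_separable_toy_reaches_perfect_training_accuracy(self, toy):
        X, y = toy
        m = fit_gbdt(X, y, M=50, depth=2)
        assert ((m.predict_score(X) > 0.5) == y).mean() == 1.0

    def test_agrees_with_independent_library_gbm(self, toy):
        """Cross-check classifications against an independently implemented
        gradient-boosting classifier on the same toy problem."""
        from sklearn.ensemble import GradientBoostingClassifier

        X, y = toy
        ours = fit_gbdt(X, y, M=50, depth=2, learning_rate=0.1)
        ref = GradientBoostingClassifier(n_estimators=50, max_depth=2,
                                         learning_rate=0.1).fit(X, y)
        assert np.array_equal(ours.predict_score(X) > 0.5, ref.predict(X) == 1)

    def test_training_loss_non_increasing(self, rng):
        X = rng.normal(size=(80, 5))
        y = (X[:, 0] + 0.3 * rng.normal(size=80) > 0).astype(float)
        m = fit_gbdt(X, y, M=40, depth=3)
        assert len(m.train_loss_curve) == 41
        assert all(np.diff(m.train_loss_curve) <= 1e-10)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_gbdt(np.zeros((5, 2)), np.ones(5), M=3)

    def test_all_but_one_identical_labels_gives_prior_dominated_model(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.zeros(20)
        y[0] = 1
        m = fit_gbdt(X, y, M=5, depth=2)
        assert m.predict_score(X).mean() < 0.5


class TestPredictScore:
    def test_zero_trees_balanced_prior_is_half(self, toy):
        X, y = toy
        m = fit_gbdt(X, y, M=0)
        assert predict_score(m, X[0]) == pytest.approx(0.5)

    def test_deterministic_and_matches_additive_formula(self, toy):
        X, y = toy
        m = fit_gbdt(X, y, M=10, depth=2)
        raw = m.base_score + m.learning_rate * sum(t.predict(X) for t in m.trees)
        assert np.allclose(m.predict_score(X), 1 / (1 + np.exp(-raw)))
        assert np.array_equal(m.predict_score(X), m.predict_score(X.copy()))

    def test_scores_strictly_inside_unit_interval(self, toy):
        X, y = toy
        s = fit_gbdt(X, y, M=30, depth=3).predict_score(X)
        assert np.all(s > 0) and np.all(s < 1)

    def test_width_mismatch_raises(self, toy):
        X, y = toy
        m = fit_gbdt(X, y, M=2)
        with pytest.raises(ValueError, match="width mismatch"):
            m.predict_score(np.zeros((3, 5)))


class TestGossSample:
    def test_a_one_keeps_everything_unit_weight(self, rng):
        g = rng.normal(size=17)
        idx, w = goss_sample(g, GossConfig(a=1.0, b=0.0), 0)
        assert np.array_equal(np.sort(idx), np.arange(17))
        assert np.all(w == 1)

    def test_counts_and_amplifier(self, rng):
        g = rng.normal(size=10)
        idx, w = goss_sample(g, GossConfig(a=0.2, b=0.3), 0)
        assert idx.size == 2 + 3
        assert np.all(w[:2] == 1.0)
        assert np.all(w[2:] == pytest.approx((1 - 0.2) / 0.3))
        top2 = np.argsort(-np.abs(g), kind="stable")[:2]
        assert set(top2) <= set(idx.tolist())

    def test_a_zero_b_one_is_a_noop(self, rng):
        g = rng.normal(size=13)
        idx, w = goss_sample(g, GossConfig(a=0.0, b=1.0), 0)
        assert np.array_equal(np.sort(idx), np.arange(13))
        assert np.allclose(w, 1.0)

    def test_invalid_fractions_raise(self):
        with pytest.raises(ValueError, match="a \\+ b"):
            GossConfig(a=0.6, b=0.6)
        with pytest.raises(ValueError, match="b > 0"):
            GossConfig(a=0.5, b=0.0)

    def test_reproducible_under_fixed_seed(self, rng):
        g = rng.normal(size=50)
        cfg = GossConfig(0.2, 0.2)
        i1, w1 = goss_sample(g, cfg, 7)
        i2, w2 = goss_sample(g, cfg, 7)
        assert np.array_equal(i1, i2) and np.array_equal(w1, w2)

    def test_weighted_gradient_sum_unbiased(self, rng):
        """Over many seeded draws the weighted subsample gradient sum matches
        the full gradient sum within 3 standard errors."""
        g = rng.normal(size=200)
        cfg = GossConfig(a=0.2, b=0.3)
        full = g.sum()
        draws = np.array([g[i] @ w for i, w in
                          (goss_sample(g, cfg, s) for s in range(600))])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - full) <= 3 * max(se, 1e-12)


class TestEfbBundle:
    def test_mutually_exclusive_features_share_a_bundle(self):
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 0]], dtype=float)
        bundles = efb_bundle(X, conflict_budget=0)
        assert len(bundles) == 1
        assert sorted(bundles[0].features) == [0, 1]

    def test_dense_features_stay_singletons(self, rng):
        X = np.abs(rng.normal(size=(20, 4))) + 0.1
        bundles = efb_bundle(X, conflict_budget=0)
        assert len(bundles) == 4
        assert all(len(b.features) == 1 for b in bundles)

    def test_conflict_budget_merges_one_conflicting_pair(self):
        # features 0 and 1 conflict in exactly one row; feature 2 is dense
        X = np.array([[1, 1, 1], [1, 0, 1], [0, 1, 1], [0, 1, 1]], dtype=float)
        assert len(efb_bundle(X, conflict_budget=0)) == 3
        assert len(efb_bundle(X, conflict_budget=1)) == 2

    def test_roundtrip_exact_without_conflicts(self, rng):
        X = np.zeros((30, 6))
        for j in range(6):  # disjoint nonzero row blocks
            X[5 * j:5 * j + 5, j] = rng.integers(1, 4, 5)
        bundles = efb_bundle(X, conflict_budget=0)
        Xb = apply_bundles(X, bundles)
        assert Xb.shape[1] == len(bundles) < 6
        assert np.allclose(reconstruct_from_bundles(Xb, bundles, 6), X)


class TestFitGossGbm:
    def test_reduces_to_plain_gbdt_without_sampling(self, rng):
        X = rng.integers(0, 2, size=(60, 12)).astype(float)
        y = (X[:, 0] + X[:, 3] >= 1).astype(float)
        plain = fit_gbdt(X, y, M=20, depth=3)
        hist = fit_goss_gbm(X, y, M=20, depth=3, goss=GossConfig(1.0, 0.0), bins=32)
        assert np.allclose(plain.predict_score(X), hist.predict_score(X))

    def test_separable_toy_reaches_perfect_accuracy(self, toy):
        X, y = toy
        m = fit_goss_gbm(X, y, M=50, depth=2, seed=0)
        assert ((m.predict_score(X) > 0.5) == y).mean() == 1.0

    def test_fixed_seed_reproduces_model(self, rng):
        X = rng.normal(size=(100, 6))
        y = (X[:, 1] > 0).astype(float)
        m1 = fit_goss_gbm(X, y, M=15, depth=2, goss=GossConfig(0.2, 0.2), seed=3)
        m2 = fit_goss_gbm(X, y, M=15, depth=2, goss=GossConfig(0.2, 0.2), seed=3)
        assert m1.to_json() == m2.to_json()

    def test_bins_below_two_raise(self, toy):
        X, y = toy
        with pytest.raises(ValueError, match="bins"):
            fit_goss_gbm(X, y, M=2, bins=1)

    def test_efb_path_predicts_through_bundles(self, rng):
        X = np.zeros((40, 8))
        for j in range(8):
            X[5 * j:5 * j + 5, j] = 1.0
        y = (X[:, :4].sum(1) > 0).astype(float)
        m = fit_goss_gbm(X, y, M=10, depth=2, use_efb=True, seed=0)
        assert m.bundles is not None and m.n_features < 8
        assert ((m.predict_score(X) > 0.5) == y).mean() >= 0.9


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, toy, rng):
        X, y = toy
        Xb = rng.integers(0, 2, size=X.shape).astype(float)
        for m in (fit_gbdt(X, y, M=8, depth=2),
                  fit_goss_gbm(X, y, M=8, depth=2, seed=1),
                  fit_goss_gbm(Xb, y, M=4, depth=2, use_efb=True, seed=1)):
            m2 = GBDTModel.from_json(m.to_json())
            assert type(m2) is type(m)
            assert np.allclose(m.predict_score(X), m2.predict_score(X))
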