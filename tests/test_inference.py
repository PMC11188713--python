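"""Mixture-density posterior estimation: arithmetic, training, recovery."""

import numpy as np
import pytest

from striatnet.inference import (InferenceConfig, MDNEstimator,
                                 best_fit_lookup, posterior_map,
                                 select_winner, train_estimator,
                                 train_restarts, weighted_mse, RestartResult)
from striatnet.synthetic import surrogate_dataset

BOX_WIDTHS = np.array([0.018, 2.0e-5])


class TestWeightedMSE:
    def test_zero_iff_equal(self):
        assert weighted_mse((0.01, 1e-5), (0.01, 1e-5)) == 0.0
        assert weighted_mse((0.01, 1e-5), (0.01, 1.1e-5)) > 0.0

    def test_inhibition_axis_arithmetic(self):
        assert weighted_mse((0.01, 1e-5), (0.011, 1e-5)) == pytest.approx(1e-6)

    def test_excitation_axis_uses_factor_900(self):
        assert weighted_mse((0.01, 1e-5), (0.01, 2e-5)) == pytest.approx(
            (900 * 1e-5) ** 2)

    def test_symmetry(self):
        a, b = (0.004, 3e-6), (0.017, 1.4e-5)
        assert weighted_mse(a, b) == weighted_mse(b, a)


@pytest.fixture(scope="module")
def surrogate_split():
    theta, x = surrogate_dataset(170, seed=11)
    return (theta[:150], x[:150]), (theta[150:], x[150:])


@pytest.fixture(scope="module")
def trained(surrogate_split):
    train, _ = surrogate_split
    cfg = InferenceConfig(n_restarts=6, holdout=20)
    results = train_restarts(train, cfg, seed=99)
    return cfg, results, select_winner(results)


class TestTraining:
    def test_deterministic_given_seed(self, surrogate_split):
        train, _ = surrogate_split
        cfg = InferenceConfig(epochs=40)
        a = train_estimator(train, cfg, seed=7)
        b = train_estimator(train, cfg, seed=7)
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.bm, b.bm)

    def test_gradients_match_finite_differences(self, rng):
        cfg = InferenceConfig(n_components=3, hidden=8)
        est = MDNEstimator(cfg, rng)
        xs = rng.standard_normal((12, 3))
        u = rng.random((12, 2))
        _, g = est._loss_grad(xs, u)
        eps = 1e-6
        for name in ("w1", "wa", "wm", "ws", "b2"):
            w = getattr(est, name)
            idx = tuple(rng.integers(0, s) for s in w.shape)
            w[idx] += eps
            lp, _ = est._loss_grad(xs, u)
            w[idx] -= 2 * eps
            lm, _ = est._loss_grad(xs, u)
            w[idx] += eps
            assert g[name][idx] == pytest.approx((lp - lm) / (2 * eps),
                                                 rel=1e-4, abs=1e-7)

    def test_single_atom_training_concentrates_posterior(self):
        theta = np.tile([[0.012, 8e-6]], (40, 1))
        x = np.tile([[0.4, 5.0, 2.0]], (40, 1)) + \
            np.random.default_rng(0).normal(0, 0.01, (40, 3))
        est = train_estimator((theta, x),
                              InferenceConfig(epochs=2000, lr=1e-2), seed=3)
        s = posterior_map(est, np.array([0.4, 5.0, 2.0]), n_samples=0)
        assert s.map_gi == pytest.approx(0.012, abs=0.001)
        assert s.map_ge == pytest.approx(8e-6, abs=1e-6)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            train_estimator((np.zeros((1, 2)), np.zeros((1, 3))),
                            InferenceConfig())


class TestPosteriorMap:
    def test_grid_density_normalizes(self, trained):
        cfg, _, win = trained
        s = posterior_map(win.estimator, np.array([0.5, 3.0, 2.0]), cfg,
                          n_samples=0)
        cell = (0.018 / cfg.grid) * (2e-5 / cfg.grid)
        assert s.joint.sum() * cell == pytest.approx(1.0, abs=0.01)
        assert (s.joint >= 0).all()

    def test_map_inside_prior_box(self, trained):
        cfg, _, win = trained
        for feats in ([0.1, 10.0, 1.0], [0.9, 0.5, 0.2], [2.0, 40.0, 9.0]):
            s = posterior_map(win.estimator, np.array(feats), cfg, n_samples=0)
            assert 0.002 <= s.map_gi <= 0.02
            assert 0.0 <= s.map_ge <= 2e-5

    def test_out_of_support_features_flagged(self, trained):
        cfg, _, win = trained
        s = posterior_map(win.estimator, np.array([50.0, -30.0, 99.0]), cfg,
                          n_samples=0)
        assert s.out_of_support

    def test_samples_inside_box_and_reproducible(self, trained):
        cfg, _, win = trained
        feats = np.array([0.5, 3.0, 2.0])
        a = posterior_map(win.estimator, feats, cfg, n_samples=500,
                          rng=np.random.default_rng(5)).samples
        b = posterior_map(win.estimator, feats, cfg, n_samples=500,
                          rng=np.random.default_rng(5)).samples
        assert np.array_equal(a, b)
        assert (a[:, 0] >= 0.002).all() and (a[:, 0] <= 0.02).all()


class TestWinnerSelection:
    def test_single_restart_returned(self, trained):
        _, results, _ = trained
        assert select_winner(results[:1]) is results[0]

    def test_minimum_holdout_mse_wins(self, trained):
        _, results, win = trained
        assert win.holdout_mse == min(r.holdout_mse for r in results)
        assert win.holdout_mse <= float(np.median(
            [r.holdout_mse for r in results]))

    def test_exact_predictor_wins(self, trained):
        _, results, _ = trained
        perfect = RestartResult(results[0].estimator, 0.0, 99)
        assert select_winner(results + [perfect]) is perfect

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            select_winner([])


class TestBestFitLookup:
    def test_exact_match_returned(self):
        theta = np.array([[0.004, 1e-6], [0.01, 1e-5], [0.018, 1.9e-5]])
        i, _ = best_fit_lookup((0.01, 1e-5), (theta, np.zeros((3, 3))))
        assert i == 1

    def test_agrees_with_exhaustive_search(self, rng):
        theta = np.column_stack([rng.uniform(0.002, 0.02, 25),
                                 rng.uniform(0, 2e-5, 25)])
        target = (0.0123, 7.7e-6)
        i, _ = best_fit_lookup(target, (theta, np.zeros((25, 3))))
        errs = [weighted_mse(t, target) for t in theta]
        assert errs[i] == min(errs)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            best_fit_lookup((0.01, 1e-5), (np.zeros((0, 2)), np.zeros((0, 3))))


class TestRecovery:
    def test_holdout_maps_recover_surrogate_truth(self, surrogate_split, trained):
        """Parameter recovery on held-out surrogate data within 10% of the
        prior range width per axis (median absolute MAP error)."""
        _, test = surrogate_split
        cfg, _, win = trained
        errs = []
        for th, xh in zip(*test):
            s = posterior_map(win.estimator, xh, cfg, n_samples=0)
            errs.append([abs(s.map_gi - th[0]), abs(s.map_ge - th[1])])
        med = np.median(errs, axis=0)
        assert med[0] < 0.10 * BOX_WIDTHS[0]
        assert med[1] < 0.10 * BOX_WIDTHS[1]
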