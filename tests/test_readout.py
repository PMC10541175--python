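"""Readout fitting procedures and the error metrics."""

import numpy as np
import pytest

from granulearn import readout as ro


def _planted(rng, M=50, P=20, Q=1):
    H = rng.standard_normal((M, P))
    w_star = rng.standard_normal((M, Q))
    return H, w_star, H.T @ w_star


class TestLeastSquares:
    def test_realizable_target_interpolated(self, rng):
        H, _, Y = _planted(rng)
        model = ro.fit_least_squares(H, Y)
        assert np.max(np.abs(model.predict(H) - Y)) < 1e-8

    def test_zero_targets_give_zero_weights(self, rng):
        H = rng.standard_normal((30, 10))
        model = ro.fit_least_squares(H, np.zeros(10))
        np.testing.assert_allclose(model.w, 0.0, atol=1e-12)

    def test_gram_form_matches_pseudo_inverse(self, rng):
        H = rng.standard_normal((200, 50))
        Y = rng.standard_normal((50, 1))
        model = ro.fit_least_squares(H, Y)     # Gram path (M > P)
        w_pinv = np.linalg.pinv(H.T) @ Y       # direct pseudo-inverse
        assert np.max(np.abs(model.w - w_pinv)) < 1e-6

    def test_residual_orthogonal_to_row_space(self, rng):
        H = rng.standard_normal((10, 40))      # underparameterized
        Y = rng.standard_normal((40, 1))
        model = ro.fit_least_squares(H, Y)
        resid = Y - model.predict(H)
        np.testing.assert_allclose(H @ resid, 0.0, atol=1e-8)


class TestRidge:
    def test_zero_alpha_equals_least_squares(self, rng):
        H = rng.standard_normal((10, 30))      # full-rank, M < P
        Y = rng.standard_normal((30, 1))
        np.testing.assert_allclose(ro.fit_ridge(H, Y, 0.0).w,
                                   ro.fit_least_squares(H, Y).w, atol=1e-8)

    def test_large_alpha_shrinks_to_zero(self, rng):
        H = rng.standard_normal((20, 10))
        Y = rng.standard_normal((10, 1))
        assert np.max(np.abs(ro.fit_ridge(H, Y, 1e8).w)) < 1e-6

    def test_matches_primal_closed_form(self, rng):
        M, P, alpha = 10, 6, 0.37
        H = rng.standard_normal((M, P))
        Y = rng.standard_normal((P, 1))
        model = ro.fit_ridge(H, Y, alpha)
        w_closed = np.linalg.solve(H @ H.T + M * alpha * np.eye(M), H @ Y)
        assert np.max(np.abs(model.w - w_closed)) < 1e-8

    def test_training_error_nondecreasing_in_alpha(self, rng):
        H = rng.standard_normal((40, 25))
        Y = rng.standard_normal((25, 1))
        errs = []
        for alpha in (0.0, 1e-3, 1e-2, 1e-1, 1.0, 10.0):
            model = ro.fit_ridge(H, Y, alpha)
            errs.append(float(np.mean((Y - model.predict(H)) ** 2)))
        assert np.all(np.diff(errs) >= -1e-10)

    def test_negative_alpha_rejected(self, rng):
        with pytest.raises(ValueError):
            ro.fit_ridge(np.ones((2, 2)), np.ones(2), -1.0)


def _pg_oracle(H, y, lam, n_iter=200_000):
    """Projected-gradient reference solver for the nonnegative program."""
    M, P = H.shape
    A = np.hstack([H.T, np.ones((P, 1))])
    L = np.linalg.norm(A, 2) ** 2 + lam
    z = np.zeros(M + 1)
    for _ in range(n_iter):
        r = A @ z - y
        g = A.T @ r
        g[:M] += lam * z[:M]
        z -= g / L
        z[:M] = np.maximum(z[:M], 0.0)
    return z


class TestNonnegative:
    def test_zero_targets_give_zero_solution(self, rng):
        H = np.abs(rng.standard_normal((15, 8)))
        model = ro.fit_nonnegative(H, np.zeros(8))
        np.testing.assert_allclose(model.w, 0.0, atol=1e-8)
        np.testing.assert_allclose(model.bias, 0.0, atol=1e-8)

    def test_objective_at_most_planted_nonnegative_solution(self, rng):
        H = np.abs(rng.standard_normal((25, 12)))
        w_star = np.abs(rng.standard_normal((25, 1)))
        y = (H.T @ w_star).ravel() + 0.4
        lam = 1e-2 * float(np.mean(H * H))
        model = ro.fit_nonnegative(H, y)

        def obj(w, b):
            r = H.T @ w + b - y
            return 0.5 * r @ r + 0.5 * lam * w @ w

        assert obj(model.w.ravel(), model.bias[0]) <= obj(w_star.ravel(), 0.4) + 1e-8

    def test_matches_projected_gradient_oracle(self, rng):
        H = np.abs(rng.standard_normal((20, 10)))
        y = np.abs(rng.standard_normal(10))
        lam = 1e-2 * float(np.mean(H * H))
        model = ro.fit_nonnegative(H, y)
        z = _pg_oracle(H, y, lam)

        def obj(w, b):
            r = H.T @ w + b - y
            return 0.5 * r @ r + 0.5 * lam * w @ w

        mine = obj(model.w.ravel(), model.bias[0])
        oracle = obj(z[:-1], z[-1])
        assert mine <= oracle + 1e-6

    def test_kkt_conditions_hold(self, rng):
        H = np.abs(rng.standard_normal((40, 15)))
        y = np.abs(rng.standard_normal(15))
        lam = 1e-2 * float(np.mean(H * H))
        model = ro.fit_nonnegative(H, y)
        w = model.w.ravel()
        r = model.predict(H).ravel() - y
        grad = H @ r + lam * w
        # stationarity on the support, nonnegative multipliers off it
        assert np.max(np.abs(grad[w > 0])) < 1e-8
        assert np.min(grad[w == 0]) > -1e-8
        assert abs(r.sum()) < 1e-8   # free bias

    def test_never_beats_unconstrained_fit(self, rng):
        H = np.abs(rng.standard_normal((6, 30)))   # underparameterized
        y = np.abs(rng.standard_normal(30))
        nn = ro.fit_nonnegative(H, y)
        ls = ro.fit_least_squares(np.vstack([H, np.ones(30)]), y)
        r_nn = nn.predict(H).ravel() - y
        r_ls = ls.predict(np.vstack([H, np.ones(30)])).ravel() - y
        assert r_nn @ r_nn >= r_ls @ r_ls - 1e-8

    def test_negative_targets_rejected(self, rng):
        with pytest.raises(ValueError):
            ro.fit_nonnegative(np.ones((3, 2)), np.array([-1.0, 1.0]))


class TestSilentFraction:
    def test_trivial_values(self):
        assert ro.silent_fraction(np.zeros(10)) == 1.0
        assert ro.silent_fraction(np.ones(10)) == 0.0
        assert ro.silent_fraction(np.array([0.0, 0.0, 1.0, 2.0])) == 0.5

    def test_substantial_and_task_ordered_in_wide_networks(self):
        """A wide expansion read out with nonnegative weights develops a
        large fraction of silent synapses, more so for random
        categorization than for smooth Gaussian-process targets."""
        from granulearn import network as net
        from granulearn import tasks

        M, fracs = 5000, {}
        for label in ("gp", "cat"):
            per_seed = []
            for seed in range(2):
                if label == "gp":
                    ds = tasks.sample_gp_task(100, 10, 3, 1.0, seed=seed)
                    y = np.abs(ds.train_targets.ravel())
                else:
                    ds = tasks.sample_random_categorization(100, 3, 0.1, seed=seed)
                    y = (ds.train_targets.ravel() + 1) / 2
                network = net.build_network(M, ds.input_dim, seed=100 + seed)
                net.calibrate_threshold(network, ds.train_inputs, 0.3)
                H = net.expand(network, ds.train_inputs).H
                per_seed.append(ro.silent_fraction(ro.fit_nonnegative(H, y).w))
            fracs[label] = np.mean(per_seed)
        assert 0.2 < fracs["gp"] < 0.9, fracs
        assert fracs["cat"] > fracs["gp"], fracs


class TestOnlineClimbingFiber:
    def test_zero_targets_keep_zero_weights(self, rng):
        H = rng.standard_normal((20, 8))
        model = ro.fit_online_cf(H, np.zeros(8), eta=0.01, n_epochs=5, seed=0)
        np.testing.assert_array_equal(model.w, 0.0)

    def test_converges_on_realizable_problem(self, rng):
        H = rng.standard_normal((50, 10))
        y = (H.T @ rng.standard_normal(50)) / 50
        model = ro.fit_online_cf(H, y, eta=0.3 / 50, n_epochs=3000, seed=1)
        err = np.mean((model.predict(H).ravel() - y) ** 2) / np.mean(y**2)
        assert err < 1e-3

    def test_tracks_least_squares_at_default_scale(self):
        """The climbing-fiber delta rule at its default operating point
        (P=30, M=10^4, eta=0.7/M, 2x10^4 epochs) reaches a test error
        within 20% of the closed-form least-squares readout."""
        from granulearn import network as net
        from granulearn import tasks

        ds = tasks.sample_gp_task(30, 300, 3, 1.0, seed=0)
        network = net.build_network(10_000, 3, seed=50)
        net.calibrate_threshold(network, ds.train_inputs, 0.3)
        H_tr = net.expand(network, ds.train_inputs).H
        H_te = net.expand(network, ds.test_inputs).H
        e_ls = ro.evaluate(ro.fit_least_squares(H_tr, ds.train_targets),
                           H_te, ds.test_targets, "continuous")
        model = ro.fit_online_cf(H_tr, ds.train_targets.ravel(),
                                 eta=0.7 / 10_000, n_epochs=20_000, seed=0)
        e_on = ro.evaluate(model, H_te, ds.test_targets, "continuous")
        assert abs(e_on - e_ls) / e_ls < 0.2

    def test_divergence_detected(self, rng):
        H = rng.standard_normal((30, 10))
        y = rng.standard_normal(10)
        with pytest.raises(RuntimeError):
            ro.fit_online_cf(H, y, eta=10.0, n_epochs=200, seed=2)


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        H, w, Y = _planted(rng)
        model = ro.ReadoutModel(w=w)
        assert ro.evaluate(model, H, Y, "continuous") == 0.0

    def test_zero_predictor_has_unit_relative_error(self, rng):
        H = rng.standard_normal((10, 20))
        Y = rng.standard_normal((20, 1))
        model = ro.ReadoutModel(w=np.zeros((10, 1)))
        assert ro.evaluate(model, H, Y, "continuous") == pytest.approx(1.0)

    def test_anti_predictor_is_always_wrong(self, rng):
        H, w, Y = _planted(rng)
        labels = np.where(Y >= 0, 1.0, -1.0)
        model = ro.ReadoutModel(w=-w)
        # signs flipped everywhere (ties at 0 measure zero for Gaussian H)
        assert ro.evaluate(model, H, labels, "categorical") == 1.0

    def test_multi_target_errors_averaged(self, rng):
        H = rng.standard_normal((10, 30))
        Y = rng.standard_normal((30, 2))
        w = np.linalg.pinv(H.T) @ Y[:, :1]
        model = ro.ReadoutModel(w=np.hstack([w, np.zeros((10, 1))]))
        err = ro.evaluate(model, H, Y, "continuous")
        e1 = np.mean((Y[:, 0] - (H.T @ w).ravel())**2) / np.mean(Y[:, 0]**2)
        assert err == pytest.approx((e1 + 1.0) / 2)

    def test_zero_target_power_raises(self, rng):
        model = ro.ReadoutModel(w=np.zeros((5, 1)))
        with pytest.raises(ValueError):
            ro.evaluate(model, np.ones((5, 4)), np.zeros((4, 1)), "continuous")
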