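"""Analytic kernel, spherical-harmonic spectra and the error predictor."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from granulearn import tasks, theory


def arc_cosine_relu_kernel(rho):
    """Closed-form zero-threshold rectified-linear kernel (oracle)."""
    rho = np.asarray(rho, dtype=float)
    return (np.sqrt(1 - rho**2) + rho * (np.pi - np.arccos(rho))) / (2 * np.pi)


class TestAnalyticKernel:
    def test_zero_threshold_matches_closed_form(self):
        rho = np.linspace(-1, 1, 21)
        np.testing.assert_allclose(theory.analytic_kernel(rho, 0.0),
                                   arc_cosine_relu_kernel(rho), atol=1e-6)

    def test_unit_diagonal_normalization(self):
        for th in (0.0, 0.8):
            assert theory.analytic_kernel(1.0, th, normalize=True) == pytest.approx(1.0)

    def test_independent_inputs_factorize(self):
        # K(0) = (E[(u - theta)_+])^2 for p = 1
        for th in (-0.5, 0.0, 0.7, 1.5):
            expected = (norm.pdf(th) - th * norm.sf(th)) ** 2
            assert theory.analytic_kernel(0.0, th) == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_overlap(self):
        rho = np.linspace(0, 1, 30)
        for th in (0.0, 0.52, 1.28):
            k = theory.analytic_kernel(rho, th)
            assert np.all(np.diff(k) >= -1e-12)

    def test_sparser_codes_separate_more(self):
        # normalized kernels order by coding level on [0, 1)
        rho = np.linspace(0.0, 0.95, 12)
        k_sparse = theory.KernelModel.from_coding_level(0.05)
        k_dense = theory.KernelModel.from_coding_level(0.45)
        lo = theory.analytic_kernel(rho, k_sparse.theta, normalize=True)
        hi = theory.analytic_kernel(rho, k_dense.theta, normalize=True)
        assert np.all(lo <= hi + 1e-12)

    def test_power_two_kernel_against_monte_carlo(self, rng):
        th, r = 0.5, 0.6
        z1 = rng.standard_normal(2_000_000)
        z2 = r * z1 + math.sqrt(1 - r**2) * rng.standard_normal(2_000_000)
        vals = np.maximum(z1 - th, 0) ** 2 * np.maximum(z2 - th, 0) ** 2
        mc, se = vals.mean(), vals.std() / math.sqrt(len(vals))
        assert abs(theory.analytic_kernel(r, th, power=2) - mc) < 3 * se

    def test_out_of_range_overlap_rejected(self):
        with pytest.raises(ValueError):
            theory.analytic_kernel(1.5, 0.0)


class TestDegeneracies:
    def test_known_values(self):
        # D=3: 2k+1 harmonics per degree; D=2: Fourier pairs
        assert theory.degeneracy(3, 0) == 1
        assert [theory.degeneracy(3, k) for k in (1, 2, 5)] == [3, 5, 11]
        assert [theory.degeneracy(2, k) for k in (0, 1, 4)] == [1, 2, 2]
        assert theory.degeneracy(6, 2) == 20

    def test_gegenbauer_normalization_at_one(self):
        t = np.array([1.0])
        for D in (2, 3, 5, 8):
            for k in (0, 1, 3, 7):
                assert theory.gegenbauer_normalized(k, D, t)[0] == pytest.approx(1.0)


class TestKernelSpectrum:
    @pytest.mark.parametrize("f,D", [(0.1, 3), (0.3, 3), (0.3, 6)])
    def test_nonnegative_and_trace_identity(self, f, D):
        km = theory.KernelModel.from_coding_level(f)
        spec = theory.kernel_eigenvalues(km, D)
        assert np.all(spec.lambdas >= 0)
        assert abs(spec.trace / km.diagonal - 1) < 0.01

    def test_coding_level_symmetry_above_degree_one(self):
        a = theory.kernel_eigenvalues(theory.KernelModel.from_coding_level(0.2), 3, 20)
        b = theory.kernel_eigenvalues(theory.KernelModel.from_coding_level(0.8), 3, 20)
        np.testing.assert_allclose(a.lambdas[2:], b.lambdas[2:], rtol=1e-4, atol=1e-10)

    def test_dense_codes_weight_low_frequencies(self):
        # relative low-frequency content grows with coding level
        sparse = theory.kernel_eigenvalues(theory.KernelModel.from_coding_level(0.05), 3, 10)
        dense = theory.kernel_eigenvalues(theory.KernelModel.from_coding_level(0.45), 3, 10)
        assert dense.lambdas[1] / dense.lambdas[5] > sparse.lambdas[1] / sparse.lambdas[5]

    def test_mercer_reconstruction(self):
        # sum_k N(D,k) lambda_k P_k(t) recovers K(t)
        km = theory.KernelModel.from_coding_level(0.3)
        spec = theory.kernel_eigenvalues(km, 3, 60)
        t = np.linspace(-0.9, 0.9, 7)
        recon = sum(spec.degeneracies[k] * spec.lambdas[k]
                    * theory.gegenbauer_normalized(k, 3, t)
                    for k in range(spec.k_max + 1))
        np.testing.assert_allclose(recon, theory.analytic_kernel(t, km.theta),
                                   rtol=0, atol=1e-4 * km.diagonal)


class TestGpTargetSpectrum:
    def test_total_power_equals_marginal_variance(self):
        for gamma in (0.5, 1.0, 2.0):
            ts = theory.gp_target_spectrum(gamma, 3)
            assert abs(ts.total_power - 1.0) < 0.01

    def test_longer_length_scales_concentrate_low_frequencies(self):
        lo = theory.gp_target_spectrum(0.5, 3)
        hi = theory.gp_target_spectrum(2.0, 3)
        frac = lambda ts: ts.degree_power[:3].sum() / ts.total_power
        assert frac(hi) > frac(lo)

    def test_nonnegative(self):
        assert np.all(theory.gp_target_spectrum(1.0, 3).mode_power >= 0)


class TestProjectTargetPower:
    def test_constant_target_is_pure_degree_zero(self, rng):
        X = tasks.sample_sphere(1500, 3, rng)
        ts = theory.project_target_power(X, np.ones(1500), 3, 6)
        assert ts.degree_power[0] == pytest.approx(1.0, rel=0.05)
        assert np.all(ts.degree_power[1:] < 0.05)

    def test_coordinate_target_is_pure_degree_one(self, rng):
        X = tasks.sample_sphere(1500, 3, rng)
        ts = theory.project_target_power(X, X[:, 0], 3, 6)
        total = ts.total_power
        assert ts.degree_power[1] / total > 0.9

    def test_gp_draw_consistent_with_analytic_spectrum(self):
        k_max, gamma = 8, 1.0
        analytic = theory.gp_target_spectrum(gamma, 3, k_max).degree_power
        draws = []
        for seed in range(12):
            ds = tasks.sample_gp_task(700, 1, 3, gamma, seed=seed)
            ts = theory.project_target_power(ds.train_inputs,
                                             ds.train_targets.ravel(), 3, k_max)
            draws.append(ts.degree_power)
        draws = np.asarray(draws)
        sem = draws.std(axis=0, ddof=1) / math.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - analytic) < 3 * sem + 0.01)


@pytest.fixture(scope="module")
def spectra():
    km = theory.KernelModel.from_coding_level(0.3)
    return (theory.kernel_eigenvalues(km, 3, 60),
            theory.gp_target_spectrum(1.0, 3, 60))


class TestGeneralizationPrediction:

    def test_infinite_data_limit_vanishes(self, spectra):
        spec, ts = spectra
        assert theory.predict_generalization_error(spec, ts, 10**6).error < 1e-3

    def test_no_data_gives_unit_normalized_error(self, spectra):
        spec, ts = spectra
        assert theory.predict_generalization_error(spec, ts, 0).error == pytest.approx(1.0)

    def test_error_decreases_with_sample_size(self, spectra):
        spec, ts = spectra
        errs = [theory.predict_generalization_error(spec, ts, P).error
                for P in (5, 20, 80, 320)]
        assert np.all(np.diff(errs) < 0)

    def test_easier_modes_contribute_less_error(self):
        degs = np.array([1.0, 1.0])
        spec = theory.KernelSpectrum(D=3, lambdas=[0.5, 0.05], degeneracies=degs)
        ts = theory.TargetSpectrum(D=3, mode_power=[0.5, 0.5], degeneracies=degs)
        pred = theory.predict_generalization_error(spec, ts, 10)
        assert pred.degree_error_shares[0] < pred.degree_error_shares[1]

    def test_invariant_under_joint_rescaling(self, spectra):
        spec, ts = spectra
        scaled = theory.KernelSpectrum(D=3, lambdas=spec.lambdas * 37.0,
                                       degeneracies=spec.degeneracies)
        a = theory.predict_generalization_error(spec, ts, 30, ridge=1e-6)
        b = theory.predict_generalization_error(scaled, ts, 30, ridge=37e-6)
        assert a.error == pytest.approx(b.error, rel=1e-8)

    def test_truncation_and_jitter_insensitivity(self):
        km = theory.KernelModel.from_coding_level(0.3)
        e = []
        for k_max in (60, 120):
            spec = theory.kernel_eigenvalues(km, 3, k_max)
            ts = theory.gp_target_spectrum(1.0, 3, k_max)
            e.append(theory.predict_generalization_error(spec, ts, 30).error)
        assert abs(e[1] - e[0]) / e[0] < 0.01
        spec = theory.kernel_eigenvalues(km, 3, 60)
        ts = theory.gp_target_spectrum(1.0, 3, 60)
        a = theory.predict_generalization_error(spec, ts, 30, ridge=1e-9 * spec.trace)
        b = theory.predict_generalization_error(spec, ts, 30, ridge=1e-10 * spec.trace)
        assert abs(a.error - b.error) / a.error < 0.01

    def test_mismatched_grids_rejected(self, spectra):
        spec, _ = spectra
        ts = theory.gp_target_spectrum(1.0, 3, 30)
        with pytest.raises(ValueError):
            theory.predict_generalization_error(spec, ts, 10)


class TestEmpiricalKernel:
    def test_single_pattern_is_mean_square_activity(self, rng):
        h = np.abs(rng.standard_normal((100, 1)))
        k = theory.empirical_kernel(h, h)
        assert k[0, 0] == pytest.approx(np.mean(h**2))

    def test_orthogonal_patterns_have_zero_overlap(self):
        H = np.zeros((4, 2))
        H[:2, 0] = 1.0
        H[2:, 1] = 1.0
        k = theory.empirical_kernel(H, H)
        assert k[0, 1] == 0.0

    def test_converges_to_analytic_kernel(self, rng):
        # wide network: finite-M kernel tracks the infinite-width curve
        # across the overlap grid, relative to K(1)
        M, f = 200_000, 0.3
        th = float(norm.ppf(1 - f))
        rho_grid = np.linspace(-0.9, 0.9, 7)
        x = np.array([1.0, 0.0, 0.0])
        Y = np.column_stack([rho_grid, np.sqrt(1 - rho_grid**2), np.zeros_like(rho_grid)])
        J = rng.standard_normal((M, 3))
        H = np.maximum(J @ np.column_stack([x[:, None], Y.T]) - th, 0.0)
        emp = theory.empirical_kernel(H[:, :1], H[:, 1:]).ravel()
        ana = theory.analytic_kernel(rho_grid, th)
        assert np.max(np.abs(emp - ana)) / theory.analytic_kernel(1.0, th) < 0.02
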