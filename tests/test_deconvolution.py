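"""Sparse recovery, GCV, tau estimation and the coordinate descent."""

import math

import numpy as np
import pytest

from edadecode.deconvolution import (
    DeconvolutionConfig,
    _gcv_focuss,
    deconvolve,
    estimate_tau,
    focuss_plus,
    gcv_focuss_plus,
    r_squared,
)
from edadecode.forward_model import (
    ImpulseTrain,
    SCRParameters,
    build_system_matrices,
    simulate_exact,
)
from oracles import best_support_exhaustive

KERNEL = SCRParameters(0.7, 3.0)


class TestRSquared:
    def test_perfect_fit_is_one(self):
        y = np.array([0.3, 1.2, 0.8, 2.0])
        assert r_squared(y, y) == 1.0

    def test_null_model_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        assert r_squared(np.array([1.0, 2.0, 3.0]),
                         np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_constant_series_is_missing(self):
        assert math.isnan(r_squared(np.ones(5), np.zeros(5)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(3), np.ones(4))


class TestSparseRecovery:
    def test_zero_signal_gives_empty_train(self):
        sysm = build_system_matrices(KERNEL, 0.0, 20, 40)
        train = focuss_plus(np.zeros(20), sysm)
        assert train.nnz == 0

    def test_single_impulse_recovered(self):
        m = 240  # 120 s at T_y = 0.5
        sysm = build_system_matrices(KERNEL, 0.0, m, 2 * m)
        u_true = np.zeros(2 * m)
        u_true[40] = 0.5
        y = sysm.B @ u_true
        train = focuss_plus(y, sysm)
        u = train.amplitudes
        support = np.flatnonzero(u > 1e-6)
        assert list(support) == [40]
        assert abs(u[40] - 0.5) / 0.5 < 0.05

    @pytest.mark.parametrize("n_grid,grid_interval,support",
                             [(12, 0.5, (3, 8)), (24, 0.25, (5, 17))])
    def test_matches_exhaustive_support_search(self, n_grid, grid_interval,
                                               support):
        """Noiseless 2-sparse problems: IRLS equals brute-force enumeration."""
        m = 12
        sysm = build_system_matrices(KERNEL, 0.0, m, n_grid, 0.5,
                                     grid_interval)
        u_true = np.zeros(n_grid)
        u_true[list(support)] = [0.8, 0.5]
        y = sysm.B @ u_true
        best_support, _ = best_support_exhaustive(sysm.B, y, 2)
        train = focuss_plus(y, sysm)
        got = tuple(np.flatnonzero(train.amplitudes > 1e-6))
        assert got == best_support

    def test_gcv_lambda_decreases_on_noiseless_data(self):
        m = 120
        sysm = build_system_matrices(KERNEL, 0.0, m, 2 * m)
        u_true = np.zeros(2 * m)
        u_true[[20, 100, 180]] = [0.6, 0.9, 0.4]
        y = sysm.B @ u_true
        u0 = focuss_plus(y, sysm)
        cfg = DeconvolutionConfig()
        _, _, info = _gcv_focuss(y, sysm.B, u0.amplitudes, cfg)
        path = info["lambda_path"]
        assert np.all(np.diff(path) <= 1e-12)  # never moves back up
        assert path[-1] < 1e-6  # settles at the small-lambda end

    def test_gcv_residual_tracks_noise_power(self, short_noisy_fixture):
        fx = short_noisy_fixture
        sysm = build_system_matrices(fx["spec"].scr_params, 0.0,
                                     fx["spec"].n_obs, fx["spec"].n_grid)
        u0 = focuss_plus(fx["noisy"], sysm)
        train, _ = gcv_focuss_plus(fx["noisy"], sysm, u0)
        resid = fx["noisy"] - sysm.observe(train.amplitudes)
        noise_power = float(fx["noise"] @ fx["noise"])
        assert 0.5 < float(resid @ resid) / noise_power < 2.0

    def test_already_optimal_start_is_a_fixed_point(self):
        m = 60
        sysm = build_system_matrices(KERNEL, 0.0, m, 2 * m)
        u_true = np.zeros(2 * m)
        u_true[30] = 0.7
        y = sysm.B @ u_true
        train, _ = gcv_focuss_plus(y, sysm, ImpulseTrain(u_true, 0.25))
        assert np.max(np.abs(train.amplitudes - u_true)) < 1e-6


class TestTauEstimation:
    def _make_problem(self, tau, seed=0, m=360):
        rng = np.random.default_rng(seed)
        u = np.zeros(2 * m)
        idx = rng.choice(2 * m - 40, size=12, replace=False)
        u[idx] = rng.uniform(0.2, 1.0, 12)
        train = ImpulseTrain(u, 0.25)
        y = simulate_exact(tau, train, 0.0, m)
        return y, train

    def test_recovers_true_constants_noiselessly(self):
        tau = SCRParameters(0.681, 2.591)
        y, train = self._make_problem(tau)
        est = estimate_tau(y, train, SCRParameters(0.7, 3.0))
        assert abs(est.tau_r - tau.tau_r) / tau.tau_r < 0.01
        assert abs(est.tau_d - tau.tau_d) / tau.tau_d < 0.01

    def test_stationary_when_started_at_truth(self):
        tau = SCRParameters(0.681, 2.591)
        y, train = self._make_problem(tau, seed=2)
        est = estimate_tau(y, train, tau)
        assert abs(est.tau_r - tau.tau_r) < 1e-6
        assert abs(est.tau_d - tau.tau_d) < 1e-6

    def test_infeasible_start_rejected(self):
        tau = SCRParameters(0.681, 2.591)
        y, train = self._make_problem(tau, seed=3)
        bad = SCRParameters.__new__(SCRParameters)
        object.__setattr__(bad, "tau_r", 0.05)
        object.__setattr__(bad, "tau_d", 3.0)
        with pytest.raises(ValueError):
            estimate_tau(y, train, bad)


class TestDeconvolve:
    def test_zero_signal_yields_empty_result(self):
        res = deconvolve(np.zeros(100), 0.5, seed=0)
        assert res.nnz == 0
        assert math.isnan(res.r_squared)

    def test_objective_path_non_increasing(self, short_deconvolution):
        for restart in short_deconvolution.restarts_summary:
            path = np.asarray(restart["objective_path"])
            assert np.all(np.diff(path) <= 1e-12 * np.abs(path[:-1]) + 1e-15)

    def test_no_amplitude_inside_floor_gap(self, short_deconvolution):
        u = short_deconvolution.impulses.amplitudes
        gap = (u > 0) & (u < 0.01)
        assert not np.any(gap)

    def test_reconstruction_shape_and_r2(self, short_noisy_fixture,
                                         short_deconvolution):
        res = short_deconvolution
        assert res.reconstruction.size == short_noisy_fixture["noisy"].size
        assert res.r_squared <= 1.0
        assert res.r_squared > 0.9

    def test_scale_equivariance(self, short_noisy_fixture):
        """Scaling the signal by c scales amplitudes by ~c, tau unchanged."""
        c = 5.0
        cfg = DeconvolutionConfig(n_restarts=3)
        cfg_scaled = DeconvolutionConfig(n_restarts=3,
                                         amplitude_floor=0.01 * c)
        base = deconvolve(short_noisy_fixture["noisy"], 0.5, config=cfg,
                          seed=4)
        scaled = deconvolve(c * short_noisy_fixture["noisy"], 0.5,
                            config=cfg_scaled, seed=4)
        assert abs(scaled.params.tau_r - base.params.tau_r) < 0.05
        assert abs(scaled.params.tau_d - base.params.tau_d) < 0.15
        a0 = base.impulses.amplitudes
        a1 = scaled.impulses.amplitudes
        common = (a0 > 0) & (a1 > 0)
        assert common.sum() >= 0.8 * max(base.nnz, scaled.nnz)
        ratio = a1[common] / a0[common]
        assert np.median(np.abs(ratio - c)) / c < 0.05

    def test_median_tau_error_across_study_below_ten_percent(self, tau_study):
        all_errs = [r.max_rel_err_pct for r in tau_study.rows]
        assert np.median(all_errs) < 10.0

    def test_impulse_count_error_within_three(self, tau_study):
        errs = [abs(r.n_impulses_hat - r.n_impulses_true)
                for r in tau_study.rows]
        assert max(errs) <= 3
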