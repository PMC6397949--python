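import numpy as np
import pytest

from blinksync import (compute_ncr, enhanced_sigma_ncr, fit_mvar,
                       integrate_ncr, participant_sigma_ncr,
                       screen_delayed_series, select_order, transfer_functions)
from blinksync.motion import MotionEnergySeries
from blinksync.ncr import MVARFit, NCRSpectrum

from conftest import as_series, simulate_var


def normal_equations_fit(x, y, order):
    """Independent OLS oracle: explicit Gram-matrix solve per equation."""
    T = len(x)
    rows = np.arange(order, T)
    X = np.column_stack(
        [v for i in range(1, order + 1) for v in (x[rows - i], y[rows - i])])
    out = {}
    for name, target in (("x", x[rows]), ("y", y[rows])):
        beta = np.linalg.solve(X.T @ X, X.T @ target)
        resid = target - X @ beta
        out[name] = (beta, resid @ resid / len(rows))
    return out


def make_fit(A_list, s2x=1.0, s2y=1.0, fs=30.0):
    A_list = [np.asarray(A, dtype=float) for A in A_list]
    return MVARFit(
        order=len(A_list),
        coeff_a=np.array([A[0, 0] for A in A_list]),
        coeff_b=np.array([A[0, 1] for A in A_list]),
        coeff_c=np.array([A[1, 0] for A in A_list]),
        coeff_d=np.array([A[1, 1] for A in A_list]),
        sigma2_ux=s2x, sigma2_uy=s2y, residual_corr=0.0, aic=0.0,
        n_samples=1000, fs=fs,
    )


class TestFitMVAR:
    def test_recovers_known_ar2_with_no_coupling(self):
        x, y = simulate_var(
            [np.array([[0.5, 0.0], [0.0, 0.3]]),
             np.array([[-0.3, 0.0], [0.0, 0.2]])],
            sigmas=(1.0, 1.0), T=10_000, seed=11)
        fit = fit_mvar(as_series(x), as_series(y), order=2)
        assert fit.coeff_a == pytest.approx([0.5, -0.3], abs=0.05)
        assert np.all(np.abs(fit.coeff_b) < 0.05)

    def test_independent_white_noise_has_null_cross_coefficients(self, rng):
        x = rng.standard_normal(8000)
        y = rng.standard_normal(8000)
        fit = fit_mvar(as_series(x), as_series(y), order=2)
        assert np.all(np.abs(fit.coeff_b) < 0.05)
        assert np.all(np.abs(fit.coeff_c) < 0.05)
        assert abs(fit.residual_corr) < 0.05

    def test_matches_normal_equations_oracle_on_toy_pair(self, rng):
        x = rng.uniform(-1, 1, 12)
        y = rng.uniform(-1, 1, 12)
        fit = fit_mvar(as_series(x), as_series(y), order=1)
        oracle = normal_equations_fit(x, y, 1)
        bx, s2x = oracle["x"]
        by, s2y = oracle["y"]
        assert fit.coeff_a[0] == pytest.approx(bx[0], abs=1e-8)
        assert fit.coeff_b[0] == pytest.approx(bx[1], abs=1e-8)
        assert fit.coeff_c[0] == pytest.approx(by[0], abs=1e-8)
        assert fit.coeff_d[0] == pytest.approx(by[1], abs=1e-8)
        assert fit.sigma2_ux == pytest.approx(s2x, rel=1e-8)
        assert fit.sigma2_uy == pytest.approx(s2y, rel=1e-8)

    def test_constant_series_raises_singular_error(self):
        x = as_series(np.zeros(100))
        y = as_series(np.random.default_rng(0).standard_normal(100))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_mvar(x, y, order=1)

    def test_requires_detrended_input(self, rng):
        x = MotionEnergySeries(rng.uniform(0, 1, 100), fs=30.0)
        with pytest.raises(ValueError, match="detrend"):
            fit_mvar(x, x, order=1)


class TestSelectOrder:
    def test_recovers_order_three_majority(self):
        A1 = np.array([[0.4, 0.2], [0.1, 0.3]])
        A2 = np.array([[-0.3, 0.0], [0.0, -0.3]])
        A3 = np.array([[0.0, 0.3], [0.25, 0.0]])
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            x, y = simulate_var([A1, A2, A3], (1.0, 1.0), T=5000, seed=seed)
            n_star, _ = select_order(as_series(x), as_series(y))
            hits += (n_star == 3)
        assert hits >= 0.9 * n_seeds

    def test_white_noise_prefers_order_one(self):
        winners = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, y = rng.standard_normal((2, 2000))
            n_star, _ = select_order(as_series(x), as_series(y))
            winners.append(n_star)
        assert np.bincount(winners).argmax() == 1

    def test_table_covers_all_candidate_orders(self, rng):
        x, y = rng.standard_normal((2, 500))
        _, table = select_order(as_series(x), as_series(y), max_order=7)
        assert len(table) == 7
        assert table["order"].tolist() == list(range(1, 8))


class TestTransferFunctions:
    def test_zero_coefficients_give_identity_transfer(self):
        fit = make_fit([np.zeros((2, 2))])
        spec = transfer_functions(fit, n_freqs=64)
        assert np.allclose(spec.alpha_sq, 1.0)
        assert np.allclose(spec.beta_sq, 0.0)
        assert spec.freqs[0] == 0.0 and spec.freqs[-1] == 15.0

    def test_scalar_ar1_closed_form_at_zero_frequency(self):
        fit = make_fit([np.array([[0.5, 0.0], [0.0, 0.0]])])
        spec = transfer_functions(fit, n_freqs=16)
        assert spec.alpha_sq[0] == pytest.approx(1.0 / (1 - 0.5) ** 2)

    def test_matches_truncated_impulse_response_oracle(self, rng):
        A1 = np.array([[0.4, 0.15], [-0.1, 0.3]])
        A2 = np.array([[-0.2, 0.05], [0.1, -0.25]])
        fit = make_fit([A1, A2])
        spec = transfer_functions(fit, n_freqs=33)
        # oracle: iterate the impulse response H_k, then evaluate its Fourier
        # sum at the grid frequencies
        L = 2048
        H = np.zeros((L, 2, 2))
        H[0] = np.eye(2)
        for k in range(1, L):
            H[k] = A1 @ H[k - 1]
            if k >= 2:
                H[k] += A2 @ H[k - 2]
        for fi, f in enumerate(spec.freqs):
            phase = np.exp(-2j * np.pi * f * np.arange(L) / fit.fs)
            Hf = np.tensordot(phase, H, axes=(0, 0))
            assert spec.alpha_sq[fi] == pytest.approx(abs(Hf[0, 0]) ** 2,
                                                      abs=1e-6)
            assert spec.beta_sq[fi] == pytest.approx(abs(Hf[0, 1]) ** 2,
                                                     abs=1e-6)

    def test_unstable_fit_reports_spectral_radius(self):
        fit = make_fit([np.array([[1.1, 0.0], [0.0, 0.5]])])
        with pytest.raises(ValueError, match="radius"):
            transfer_functions(fit)


class TestComputeNCR:
    def test_zero_cross_coefficients_give_zero_ncr(self):
        fit = make_fit([np.array([[0.5, 0.0], [0.0, 0.4]])], s2x=1.0, s2y=2.0)
        spec = compute_ncr(fit)
        assert np.all(spec.ncr_y_to_x == 0.0)
        assert np.all(spec.ncr_x_to_y == 0.0)

    def test_symmetric_fit_gives_symmetric_ncr(self):
        fit = make_fit([np.array([[0.4, 0.2], [0.2, 0.4]])], s2x=1.3, s2y=1.3)
        spec = compute_ncr(fit)
        assert spec.ncr_y_to_x == pytest.approx(spec.ncr_x_to_y, abs=1e-12)

    def test_ncr_bounded_on_random_stable_fits(self, rng):
        checked = 0
        while checked < 30:
            A = rng.uniform(-0.6, 0.6, (2, 2))
            fit = make_fit([A], s2x=rng.uniform(0.5, 2),
                           s2y=rng.uniform(0.5, 2))
            if fit.companion_radius() >= 0.98:
                continue
            spec = compute_ncr(fit)
            for arr in (spec.ncr_y_to_x, spec.ncr_x_to_y):
                assert np.all(arr >= 0.0) and np.all(arr <= 1.0)
            checked += 1

    def test_matches_noise_silencing_simulation_oracle(self):
        """NCR equals the spectral share obtained by silencing one source.

        Simulate the VAR twice with identical coefficients — once full, once
        with the y-innovation silenced — and compare the band-averaged Welch
        power of x against the model-implied decomposition.
        """
        from scipy.signal import welch

        A = np.array([[0.5, 0.4], [0.0, 0.6]])
        s2x, s2y = 1.0, 4.0
        fs = 30.0
        T = 200_000

        rng = np.random.default_rng(42)
        eps = rng.standard_normal((T, 2)) * np.sqrt([s2x, s2y])
        xy_full = np.zeros((T, 2))
        xy_sil = np.zeros((T, 2))
        eps_sil = eps.copy()
        eps_sil[:, 1] = 0.0
        for t in range(1, T):
            xy_full[t] = A @ xy_full[t - 1] + eps[t]
            xy_sil[t] = A @ xy_sil[t - 1] + eps_sil[t]

        fit = make_fit([A], s2x=s2x, s2y=s2y, fs=fs)
        spec = compute_ncr(fit, n_freqs=129)
        model_total = spec.alpha_sq * s2x + spec.beta_sq * s2y

        f_w, p_full = welch(xy_full[1000:, 0], fs=fs, nperseg=256)
        _, p_sil = welch(xy_sil[1000:, 0], fs=fs, nperseg=256)
        # Welch is a one-sided density: 2/fs times the model's |H|^2-weighted
        # innovation variances; compare band-averaged power within 10%
        grid = np.interp(f_w, spec.freqs, model_total)
        band = slice(2, 120)
        assert np.mean(p_full[band]) == pytest.approx(
            2.0 / fs * np.mean(grid[band]), rel=0.1)
        # silenced share: power of x driven by its own noise only
        own_share = np.interp(
            f_w, spec.freqs, 1.0 - spec.ncr_y_to_x)
        emp_share = p_sil[band] / p_full[band]
        assert np.mean(emp_share) == pytest.approx(
            np.mean(own_share[band]), rel=0.1)


class TestIntegrateNCR:
    def _spec(self, freqs, ncr, fs=30.0):
        n = len(freqs)
        z = np.zeros(n)
        return NCRSpectrum(freqs=np.asarray(freqs, float),
                           ncr_y_to_x=np.asarray(ncr, float),
                           ncr_x_to_y=np.asarray(ncr, float),
                           alpha_sq=z, beta_sq=z, gamma_sq=z, delta_sq=z,
                           fs=fs)

    def test_constant_ncr_integrates_to_c_times_nyquist(self):
        spec = self._spec(np.linspace(0, 15, 513), np.full(513, 0.4))
        assert integrate_ncr(spec).value == pytest.approx(0.4 * 15.0)

    def test_zero_ncr_integrates_to_zero(self):
        spec = self._spec(np.linspace(0, 15, 64), np.zeros(64))
        assert integrate_ncr(spec).value == 0.0

    def test_piecewise_linear_matches_hand_trapezoid(self):
        # hand arithmetic: widths 1, heights (0,.5,1,.5,0)
        # 0.25 + 0.75 + 0.75 + 0.25 = 2.0
        spec = self._spec([0, 1, 2, 3, 4], [0.0, 0.5, 1.0, 0.5, 0.0])
        assert integrate_ncr(spec).value == pytest.approx(2.0)


class TestParticipantSummary:
    def _coupled_blocks(self, n_blocks, seed0=0, gain=0.35):
        A = np.array([[0.3, gain], [0.0, 0.4]])
        out = []
        for s in range(n_blocks):
            x, y = simulate_var([A], (1.0, 1.0), T=450, seed=seed0 + s)
            # shift to the raw (non-negative) scale; detrending undoes it
            out.append((as_series(x - x.min(), detrended=False),
                        as_series(y - y.min(), detrended=False)))
        return out

    def test_identical_blocks_mean_equals_single_value(self):
        block = self._coupled_blocks(1)[0]
        mean1, t1 = participant_sigma_ncr([block])
        mean32, t32 = participant_sigma_ncr([block] * 32)
        assert len(t32) == 32
        assert mean32 == pytest.approx(mean1)

    def test_mean_is_arithmetic_mean_of_block_values(self):
        blocks = self._coupled_blocks(5)
        mean, table = participant_sigma_ncr(blocks)
        assert mean == pytest.approx(table["sigma_ncr"].mean())
        assert len(table) == 5

    def test_failed_blocks_are_skipped_not_fatal(self):
        blocks = self._coupled_blocks(3)
        dead = (as_series(np.zeros(450), detrended=False),
                as_series(np.zeros(450), detrended=False))
        mean, table = participant_sigma_ncr(blocks + [dead])
        assert len(table) == 3
        assert np.isfinite(mean)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            participant_sigma_ncr([])


class TestEnhancement:
    def test_arithmetic(self):
        assert enhanced_sigma_ncr(1.0, 1.0) == 0.0
        assert enhanced_sigma_ncr(1.2, 0.4) == pytest.approx(0.8)

    def test_coupled_condition_enhanced_over_uncoupled_baseline(self):
        """With coupling on in one condition and off in the baseline, the
        enhancement is positive in the clear majority of seeds."""
        A_on = np.array([[0.3, 0.4], [0.0, 0.4]])
        A_off = np.array([[0.3, 0.0], [0.0, 0.4]])
        wins = 0
        n_seeds = 20
        for s in range(n_seeds):
            vals = {}
            for name, A in (("on", A_on), ("off", A_off)):
                x, y = simulate_var([A], (1.0, 1.0), T=450, seed=100 + s)
                m, _ = participant_sigma_ncr(
                    [(as_series(x - x.min(), detrended=False),
                      as_series(y - y.min(), detrended=False))])
                vals[name] = m
            wins += enhanced_sigma_ncr(vals["on"], vals["off"]) > 0
        assert wins >= 0.8 * n_seeds


def test_screen_series_is_partner_delayed():
    s = as_series(np.arange(10.0), detrended=False)
    scr = screen_delayed_series(s, delay_s=20.0)
    assert scr.t0 == pytest.approx(s.t0 + 20.0)
    assert np.array_equal(scr.values, s.values)
    with pytest.raises(ValueError):
        screen_delayed_series(s, delay_s=0.0)
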