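"""Akaike noise-contribution-ratio (NCR) spectral causality.

A pair of stationary series x(t), y(t) is modelled with a bivariate
autoregression of order N,

    x(t) = sum_i a_i x(t-i) + sum_i b_i y(t-i) + u_x(t)
    y(t) = sum_i c_i x(t-i) + sum_i d_i y(t-i) + u_y(t),

with innovation variances sigma^2_ux, sigma^2_uy.  Writing the transfer
matrix H(f) = [I - sum_k A_k e^{-2*pi*i*f*k/fs}]^{-1} with
A_k = [[a_k, b_k], [c_k, d_k]], the power spectrum of x splits into a part
driven by its own innovations and a part driven by the partner's:

    S_x(f) = |H11(f)|^2 sigma^2_ux + |H12(f)|^2 sigma^2_uy.

The noise contribution ratio

    NCR_{y->x}(f) = |H12(f)|^2 sigma^2_uy / S_x(f)

is the fraction of x's spectral density at frequency f attributable to y's
innovations — a directional influence measure in [0, 1].  Its trapezoidal
integral over [0, fs/2], denoted sigma-NCR (units Hz), is the scalar
directional-influence index summarised per block and averaged per
participant and condition.

The model order N is chosen to minimise the multivariate Gaussian AIC over
a caller-set range (default 1-10), with all candidate orders evaluated on
the common sample t = max_order+1..T so their likelihoods are comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .motion import MotionEnergySeries, detrend_linear

logger = logging.getLogger(__name__)

#: residual cross-correlation above which the independent-noise assumption
#: behind the NCR formula is flagged
RESIDUAL_CORR_WARN = 0.2


@dataclass
class MVARFit:
    """Bivariate AR(N) least-squares fit.

    Coefficient arrays are indexed by lag-1: ``coeff_a[i]`` multiplies
    x(t-i-1) in the x equation, etc.
    """

    order: int
    coeff_a: np.ndarray
    coeff_b: np.ndarray
    coeff_c: np.ndarray
    coeff_d: np.ndarray
    sigma2_ux: float
    sigma2_uy: float
    residual_corr: float
    aic: float
    n_samples: int
    fs: float

    def companion_radius(self) -> float:
        """Spectral radius of the VAR companion matrix (< 1 iff stable)."""
        N = self.order
        comp = np.zeros((2 * N, 2 * N))
        for k in range(N):
            comp[0:2, 2 * k:2 * k + 2] = self.lag_matrix(k + 1)
        if N > 1:
            comp[2:, :-2] = np.eye(2 * (N - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def lag_matrix(self, k: int) -> np.ndarray:
        """A_k = [[a_k, b_k], [c_k, d_k]] for lag k (1-based)."""
        i = k - 1
        return np.array([[self.coeff_a[i], self.coeff_b[i]],
                         [self.coeff_c[i], self.coeff_d[i]]])


@dataclass
class NCRSpectrum:
    """NCR and squared transfer magnitudes on a frequency grid [0, fs/2]."""

    freqs: np.ndarray
    ncr_y_to_x: np.ndarray
    ncr_x_to_y: np.ndarray
    alpha_sq: np.ndarray   # |H11|^2
    beta_sq: np.ndarray    # |H12|^2
    gamma_sq: np.ndarray   # |H21|^2
    delta_sq: np.ndarray   # |H22|^2
    fs: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "freq_hz": self.freqs,
            "ncr_y_to_x": self.ncr_y_to_x,
            "ncr_x_to_y": self.ncr_x_to_y,
        })


@dataclass
class SigmaNCR:
    """Integrated NCR over [0, fs/2]; units Hz."""

    value: float
    direction: str = ""
    block_index: int | None = None
    run_index: int | None = None


def _lag_design(x: np.ndarray, y: np.ndarray, order: int,
                t_start: int) -> tuple[np.ndarray, np.ndarray]:
    """Regression design for rows t = t_start..T-1 (0-based), lags 1..order."""
    T = len(x)
    rows = np.arange(t_start, T)
    cols = []
    for i in range(1, order + 1):
        cols.append(x[rows - i])
        cols.append(y[rows - i])
    X = np.column_stack(cols)
    Y = np.column_stack([x[rows], y[rows]])
    return X, Y


def fit_mvar(
    x: MotionEnergySeries,
    y: MotionEnergySeries,
    order: int,
    _t_start: int | None = None,
) -> MVARFit:
    """Joint least-squares fit of the bivariate AR(N).

    Equivalent to per-equation OLS on the shared lag design; the estimation
    sample is t = N+1..T (``_t_start`` overrides it so that order selection
    can hold the sample fixed across candidate orders).  Residual variances
    use denominator equal to the number of regression rows.
    """
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if x.fs != y.fs:
        raise ValueError("sampling rates differ")
    if not (x.detrended and y.detrended):
        raise ValueError("detrend both series before MVAR fitting")
    T = len(x)
    if order < 1:
        raise ValueError("order must be >= 1")
    if T <= 10 * order:
        raise ValueError(f"need T > 10*N; got T={T}, N={order}")
    t_start = order if _t_start is None else _t_start
    X, Y = _lag_design(x.values, y.values, order, t_start)
    n_rows = X.shape[0]

    # singular design (e.g. a constant series) must fail loudly
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular lag design (rank {rank} < {X.shape[1]}); "
            "constant or collinear series"
        )
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    cov = resid.T @ resid / n_rows
    s2x, s2y = float(cov[0, 0]), float(cov[1, 1])
    if s2x <= 0 or s2y <= 0:
        raise np.linalg.LinAlgError("zero residual variance; degenerate series")
    rcorr = float(cov[0, 1] / np.sqrt(s2x * s2y))
    if abs(rcorr) > RESIDUAL_CORR_WARN:
        logger.warning(
            "residual cross-correlation %.3f exceeds %.1f; the NCR formula "
            "assumes independent innovations", rcorr, RESIDUAL_CORR_WARN,
        )
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("residual covariance not positive definite")
    aic = n_rows * logdet + 2 * (4 * order + 2)

    # columns alternate x-lag, y-lag; row 0 of B.T is the x equation
    bx = B[:, 0]
    by = B[:, 1]
    return MVARFit(
        order=order,
        coeff_a=bx[0::2].copy(), coeff_b=bx[1::2].copy(),
        coeff_c=by[0::2].copy(), coeff_d=by[1::2].copy(),
        sigma2_ux=s2x, sigma2_uy=s2y,
        residual_corr=rcorr, aic=float(aic),
        n_samples=n_rows, fs=x.fs,
    )


def select_order(
    x: MotionEnergySeries,
    y: MotionEnergySeries,
    max_order: int = 10,
) -> tuple[int, pd.DataFrame]:
    """AIC order selection on a common estimation sample.

    Every candidate order 1..max_order is fitted on t = max_order+1..T so the
    AIC values share their data; AIC = n * ln det(residual covariance)
    + 2*(4N + 2).  Ties go to the smallest order.
    Returns (N*, table of per-order AIC).
    """
    if len(x) <= 10 * max_order:
        raise ValueError(f"need T > 10*max_order; got T={len(x)}")
    rows = []
    best_n, best_aic = None, np.inf
    for n in range(1, max_order + 1):
        fit = fit_mvar(x, y, n, _t_start=max_order)
        rows.append((n, fit.aic))
        if fit.aic < best_aic - 1e-12:
            best_n, best_aic = n, fit.aic
    table = pd.DataFrame(rows, columns=["order", "aic"])
    return best_n, table


def transfer_functions(fit: MVARFit, n_freqs: int = 513) -> NCRSpectrum:
    """Transfer matrix H(f) on a uniform grid over [0, fs/2].

    H(f) = [I - sum_k A_k e^{-2*pi*i*f*k/fs}]^{-1}, evaluated by direct
    inversion of the 2x2 characteristic matrix — mathematically identical to
    Fourier-transforming the (infinite) impulse response.  Requires a stable
    fit; NCR entries are left as NaN for :func:`compute_ncr` to fill.
    """
    if n_freqs < 2:
        raise ValueError("n_freqs must be >= 2")
    rho = fit.companion_radius()
    if rho >= 1.0:
        raise ValueError(
            f"unstable MVAR fit: companion spectral radius {rho:.4f} >= 1"
        )
    freqs = np.linspace(0.0, fit.fs / 2.0, n_freqs)
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, fit.order + 1)) / fit.fs)
    # characteristic matrix A(f) = I - sum_k A_k z^k, per frequency
    A = np.zeros((n_freqs, 2, 2), dtype=complex)
    A[:, 0, 0] = 1 - z @ fit.coeff_a
    A[:, 0, 1] = -(z @ fit.coeff_b)
    A[:, 1, 0] = -(z @ fit.coeff_c)
    A[:, 1, 1] = 1 - z @ fit.coeff_d
    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
    H11 = A[:, 1, 1] / det
    H12 = -A[:, 0, 1] / det
    H21 = -A[:, 1, 0] / det
    H22 = A[:, 0, 0] / det
    nan = np.full(n_freqs, np.nan)
    return NCRSpectrum(
        freqs=freqs,
        ncr_y_to_x=nan.copy(), ncr_x_to_y=nan.copy(),
        alpha_sq=np.abs(H11) ** 2, beta_sq=np.abs(H12) ** 2,
        gamma_sq=np.abs(H21) ** 2, delta_sq=np.abs(H22) ** 2,
        fs=fit.fs,
    )


def compute_ncr(fit: MVARFit, n_freqs: int = 513) -> NCRSpectrum:
    """NCR in both directions from the fit's transfer functions.

    NCR_{y->x}(f) = |H12|^2 s2y / (|H11|^2 s2x + |H12|^2 s2y) and
    symmetrically for x->y.  Positive innovation variances and a stable fit
    make the denominators strictly positive.
    """
    spec = transfer_functions(fit, n_freqs)
    den_x = spec.alpha_sq * fit.sigma2_ux + spec.beta_sq * fit.sigma2_uy
    den_y = spec.gamma_sq * fit.sigma2_ux + spec.delta_sq * fit.sigma2_uy
    assert np.all(den_x > 0) and np.all(den_y > 0), "degenerate spectrum"
    spec.ncr_y_to_x = spec.beta_sq * fit.sigma2_uy / den_x
    spec.ncr_x_to_y = spec.gamma_sq * fit.sigma2_ux / den_y
    return spec


def integrate_ncr(spectrum: NCRSpectrum, direction: str = "y->x") -> SigmaNCR:
    """Trapezoidal integral of NCR over [0, fs/2] (units Hz)."""
    ncr = spectrum.ncr_y_to_x if direction == "y->x" else spectrum.ncr_x_to_y
    if np.any(np.isnan(ncr)):
        raise ValueError("spectrum lacks NCR values; use compute_ncr")
    value = float(np.trapezoid(ncr, spectrum.freqs))
    return SigmaNCR(value=value, direction=direction)


def block_sigma_ncr(
    x_block: MotionEnergySeries,
    y_block: MotionEnergySeries,
    max_order: int = 10,
    n_freqs: int = 513,
) -> tuple[SigmaNCR, SigmaNCR, MVARFit]:
    """Detrend, select order, fit and integrate NCR for one block pair.

    Returns (sigma NCR y->x, sigma NCR x->y, fit).
    """
    xd = x_block if x_block.detrended else detrend_linear(x_block)
    yd = y_block if y_block.detrended else detrend_linear(y_block)
    n_star, _ = select_order(xd, yd, max_order)
    fit = fit_mvar(xd, yd, n_star)
    spec = compute_ncr(fit, n_freqs)
    return (integrate_ncr(spec, "y->x"), integrate_ncr(spec, "x->y"), fit)


def participant_sigma_ncr(
    block_series_pairs: list[tuple[MotionEnergySeries, MotionEnergySeries]],
    direction: str = "y->x",
    max_order: int = 10,
    n_freqs: int = 513,
) -> tuple[float, pd.DataFrame]:
    """Mean sigma-NCR across blocks, plus the per-block table.

    Each block runs detrend -> AIC order selection -> fit -> NCR ->
    trapezoidal integration.  Blocks whose fit is unstable or singular are
    skipped with a logged warning and excluded from the mean.
    """
    if not block_series_pairs:
        raise ValueError("need at least one block pair")
    rows = []
    for k, (xb, yb) in enumerate(block_series_pairs):
        try:
            s_yx, s_xy, fit = block_sigma_ncr(xb, yb, max_order, n_freqs)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("block %d skipped: %s", k, exc)
            continue
        val = s_yx.value if direction == "y->x" else s_xy.value
        rows.append((k, fit.order, val, fit.residual_corr))
    table = pd.DataFrame(
        rows, columns=["block", "order", "sigma_ncr", "residual_corr"]
    )
    if table.empty:
        warnings.warn("all blocks failed to fit; returning NaN")
        return float("nan"), table
    return float(table["sigma_ncr"].mean()), table


def enhanced_sigma_ncr(condition_value: float, rest_value: float) -> float:
    """Enhancement: a condition's sigma-NCR minus the REST baseline."""
    return condition_value - rest_value


def screen_delayed_series(
    partner: MotionEnergySeries, delay_s: float = 20.0
) -> MotionEnergySeries:
    """Motion-energy series of the replayed screen image.

    During delayed replay the screen shows the partner's face ``delay_s``
    seconds in the past, so the screen series at time t equals the partner
    series at t - delay_s.  Implemented as a time shift: the returned series
    carries the same values with t0 advanced by the delay.  Use it with
    block segmentation to build the screen->face causality input.
    """
    if delay_s <= 0:
        raise ValueError("delay must be positive")
    return replace(partner, values=partner.values.copy(),
                   t0=partner.t0 + delay_s)
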