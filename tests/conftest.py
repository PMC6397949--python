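import numpy as np
import pytest

from blinksync import make_block_schedule
from blinksync.motion import MotionEnergySeries


@pytest.fixture
def canonical_schedule():
    """The 4-run design: 30 s REST + 24 x 20 s blocks = 510 s per run."""
    return make_block_schedule(seed=7, expected_run_length_s=510.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def simulate_var(coeffs, sigmas, T, seed, burn=200):
    """Simulate a bivariate VAR given lag matrices A_k and innovation SDs.

    Independent of the package's estimation path; used as ground truth.
    """
    rng = np.random.default_rng(seed)
    N = len(coeffs)
    n = T + burn
    xy = np.zeros((n, 2))
    eps = rng.standard_normal((n, 2)) * np.asarray(sigmas)
    for t in range(N, n):
        acc = eps[t].copy()
        for k, A in enumerate(coeffs, start=1):
            acc += A @ xy[t - k]
        xy[t] = acc
    return xy[burn:, 0], xy[burn:, 1]


def as_series(values, fs=30.0, detrended=True):
    return MotionEnergySeries(np.asarray(values, dtype=float), fs=fs,
                              detrended=detrended)
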