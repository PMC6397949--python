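"""Directional influence between two blink series via spectral causality.

Simulates a dyad in which participant 1 drives participant 2 (one-way
coupling), runs the full per-block chain — detrend, AIC order selection,
bivariate autoregression, noise-contribution-ratio spectrum, trapezoidal
integration — and compares the influence index in both directions.
"""

import logging

import numpy as np

logging.disable(logging.WARNING)  # per-block diagnostics are chatty

from blinksync import DyadSimConfig, simulate_coupled_blinks
from blinksync.experiments import dyad_block_series
from blinksync.ncr import block_sigma_ncr

config = DyadSimConfig(seed=3, duration=30.0 + 32 * 15.0 + 1.0,
                       coupling_gain_12=2.0, coupling_gain_21=0.0)
dyad = simulate_coupled_blinks(config)

blocks_1 = dyad_block_series(dyad.events_1, n_blocks=32)
blocks_2 = dyad_block_series(dyad.events_2, n_blocks=32)

s12, s21, orders = [], [], []
for x2, x1 in zip(blocks_2, blocks_1):
    try:
        # x = participant 2's series, y = participant 1's: y->x is "1 drives 2"
        syx, sxy, fit = block_sigma_ncr(x2, x1)
    except (np.linalg.LinAlgError, ValueError):
        continue
    s12.append(syx.value)
    s21.append(sxy.value)
    orders.append(fit.order)

print(f"analysable blocks: {len(s12)} of 32")
print(f"AIC-selected orders: median {int(np.median(orders))}, "
      f"range {min(orders)}-{max(orders)}")
print(f"influence 1 -> 2 (planted, gain 2.0): "
      f"mean sigma-NCR = {np.mean(s12):.3f} Hz")
print(f"influence 2 -> 1 (absent):           "
      f"mean sigma-NCR = {np.mean(s21):.3f} Hz")
print("sigma-NCR integrates the noise contribution ratio over 0-15 Hz; the "
      "planted direction should exceed the silent one, on top of a common "
      "finite-sample baseline")
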