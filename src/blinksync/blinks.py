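"""Blink-event detection from motion-energy series.

A blink shows up in eye-region motion energy as a short positive pulse
(eyelid closing, then re-opening).  Events are local maxima whose prominence
clears a threshold, pruned so that no two events sit closer than a minimum
separation — a blink lasts 200-400 ms, so two maxima within that span belong
to one blink.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .design import BlockSchedule
from .motion import MotionEnergySeries

#: lower bound of the physiological blink duration, s
DEFAULT_MIN_SEPARATION_S = 0.2
#: prominence threshold as a multiple of the series' median absolute deviation
MAD_PROMINENCE_FACTOR = 5.0


@dataclass
class BlinkEvents:
    """Detected blink times (s, strictly increasing) with peak prominences."""

    times: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.prominences = np.asarray(self.prominences, dtype=float)
        if self.times.shape != self.prominences.shape:
            raise ValueError("times and prominences must align")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times,
                             "prominence": self.prominences})


def detect_blinks(
    series: MotionEnergySeries,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    min_prominence: float | None = None,
) -> BlinkEvents:
    """Peak detection with prominence threshold and greedy separation pruning.

    When ``min_prominence`` is None it is set to 5x the median absolute
    deviation of the series — an automatic stand-in for visual verification
    of each peak.  On a separation conflict the taller peak wins; on an exact
    height tie, the earlier one.
    """
    if series.detrended:
        raise ValueError("detect blinks on the raw (non-detrended) series")
    if len(series) < 3:
        raise ValueError("series too short for peak detection")
    if min_separation_s <= 0:
        raise ValueError("min_separation_s must be positive")
    v = series.values
    if min_prominence is None:
        mad = np.median(np.abs(v - np.median(v)))
        min_prominence = MAD_PROMINENCE_FACTOR * mad
        if min_prominence <= 0:
            # noise-free footage (e.g. rendered synthetic frames) has MAD 0;
            # fall back to half the series maximum, or reject everything on
            # a fully silent series
            min_prominence = 0.5 * v.max() if v.max() > 0 else np.inf
    elif min_prominence <= 0:
        raise ValueError("min_prominence must be positive")

    peaks, props = find_peaks(v, prominence=min_prominence)
    if len(peaks) == 0:
        return BlinkEvents(np.empty(0), np.empty(0))

    # greedy pruning: taller peaks claim their exclusion zone first
    order = sorted(range(len(peaks)), key=lambda i: (-v[peaks[i]], peaks[i]))
    min_gap = min_separation_s * series.fs
    kept: list[int] = []
    for i in order:
        if all(abs(peaks[i] - peaks[j]) >= min_gap for j in kept):
            kept.append(i)
    kept.sort(key=lambda i: peaks[i])
    idx = peaks[kept]
    return BlinkEvents(times=series.t0 + idx / series.fs,
                       prominences=props["prominences"][kept])


def blinks_per_block(
    events: BlinkEvents,
    schedule: BlockSchedule,
    condition: str,
    window_s: float = 15.0,
    run: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Count events in the final ``window_s`` seconds of each matching block.

    Returns the per-block table (block order follows onsets) and the mean
    count across blocks — the per-participant blink-count measure.  Events
    and schedule must share a clock (one run).
    """
    rows = []
    for k, b in enumerate(schedule.for_condition(condition)):
        if b.run != run:
            continue
        lo = b.end - window_s
        n = int(np.sum((events.times >= lo) & (events.times < b.end)))
        rows.append((k, condition, b.onset, n))
    table = pd.DataFrame(rows, columns=["block", "condition", "onset_s", "count"])
    mean = float(table["count"].mean()) if len(table) else 0.0
    return table, mean
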