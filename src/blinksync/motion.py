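"""Motion-energy extraction from eye-region video.

Motion energy at frame k+1 is the mean over a region of interest (ROI) of
the absolute frame-to-frame intensity difference |I_{k+1} - I_k|.  It is a
scalar proxy for movement in the ROI; with the ROI placed over the eyes it
rises sharply during a blink and is zero for a static scene.  The resulting
series is segmented per condition block (keeping only the final seconds of
each block, where luminance has stabilised after the condition switch) and
linearly detrended before any autoregressive modelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .design import BlockSchedule


@dataclass
class FrameStack:
    """Ordered grayscale frames (T, H, W) sampled at ``fs`` Hz."""

    frames: np.ndarray
    fs: float
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 4:  # color -> luma (ITU-R BT.601)
            w = np.array([0.299, 0.587, 0.114])
            self.frames = self.frames @ w
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (T>=2, H, W)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite pixel intensities")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.frames.shape[0] / self.fs

    @classmethod
    def from_video(cls, path, fs: float | None = None) -> "FrameStack":
        frames = iio.imread(path)
        meta = iio.immeta(path) if fs is None else {}
        fs = fs if fs is not None else float(meta.get("fps", 30.0))
        return cls(frames=np.asarray(frames, dtype=float), fs=fs)

    def to_video(self, path, codec_fps: int | None = None) -> None:
        arr = np.clip(self.frames, 0, 255).astype(np.uint8)
        iio.imwrite(path, arr, fps=codec_fps or int(round(self.fs)))


@dataclass(frozen=True)
class ROIWindow:
    """Rectangular pixel window, 0-based, half-open."""

    top: int
    left: int
    height: int
    width: int

    def validate(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        if self.height <= 0 or self.width <= 0:
            raise ValueError("empty ROI")
        if self.top < 0 or self.left < 0 or self.top + self.height > h \
                or self.left + self.width > w:
            raise ValueError(f"ROI {self} outside frame {frame_shape}")

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.top, self.top + self.height),
                slice(self.left, self.left + self.width))


def auto_roi(stack: FrameStack, height: int, width: int) -> ROIWindow:
    """Place an ROI of the given size at the maximum-temporal-variance spot.

    Convenience for synthetic footage; real recordings take a manual ROI.
    """
    var = stack.frames.var(axis=0)
    H, W = var.shape
    if height > H or width > W:
        raise ValueError("ROI larger than frame")
    csum = np.cumsum(np.cumsum(np.pad(var, ((1, 0), (1, 0))), axis=0), axis=1)
    windows = (csum[height:, width:] - csum[:-height, width:]
               - csum[height:, :-width] + csum[:-height, :-width])
    top, left = np.unravel_index(np.argmax(windows), windows.shape)
    return ROIWindow(int(top), int(left), height, width)


@dataclass
class MotionEnergySeries:
    """Uniformly sampled scalar motion-energy series.

    ``t0`` is the time of the first sample; sample k sits at t0 + k/fs.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    detrended: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite motion-energy values")
        if not self.detrended and np.any(self.values < 0):
            raise ValueError("raw motion energy must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path, sidecar: bool = True) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False
        )
        if sidecar:
            meta = {"fs": self.fs, "t0": self.t0, "detrended": self.detrended}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh)


def compute_motion_energy(stack: FrameStack, roi: ROIWindow) -> MotionEnergySeries:
    """Mean absolute frame-difference over the ROI.

    Output has length T-1; the value from frames (k, k+1) is stamped at
    frame k+1 — the instant at which the motion becomes observable — so a
    blink's motion-energy onset is never earlier than the blink itself.
    """
    roi.validate(stack.frames.shape[1:])
    sl = roi.slices()
    patch = stack.frames[:, sl[0], sl[1]].astype(float)
    me = np.abs(np.diff(patch, axis=0)).mean(axis=(1, 2))
    return MotionEnergySeries(
        values=me, fs=stack.fs, t0=stack.origin_time + 1.0 / stack.fs
    )


def segment_blocks(
    series: MotionEnergySeries,
    schedule: BlockSchedule,
    condition: str,
    analysis_window_s: float = 15.0,
    run: int | None = None,
) -> list[MotionEnergySeries]:
    """Cut out the final ``analysis_window_s`` seconds of each matching block.

    ``series`` is interpreted on the clock of a single run (``run`` selects
    which run's blocks apply; by default run 0 when the schedule has one run,
    otherwise ``run`` is required).  Each emitted sub-series covers
    [end - window, end) of its block: round(window * fs) samples.
    """
    if run is None:
        if schedule.n_runs != 1:
            raise ValueError("run index required for multi-run schedules")
        run = 0
    out: list[MotionEnergySeries] = []
    n_win = int(round(analysis_window_s * series.fs))
    for b in schedule.for_condition(condition):
        if b.run != run:
            continue
        if b.duration < analysis_window_s - 1e-9:
            raise ValueError(
                f"block {b} shorter than analysis window {analysis_window_s} s"
            )
        start_t = b.end - analysis_window_s
        i0 = int(np.ceil((start_t - series.t0) * series.fs - 1e-9))
        i0 = max(i0, 0)
        if i0 + n_win > len(series):
            raise ValueError(f"block {b} extends past the series")
        out.append(
            MotionEnergySeries(
                values=series.values[i0:i0 + n_win].copy(),
                fs=series.fs,
                t0=series.t0 + i0 / series.fs,
                detrended=series.detrended,
            )
        )
    return out


def detrend_linear(series: MotionEnergySeries) -> MotionEnergySeries:
    """Subtract the least-squares straight line; flags the result detrended.

    A constant series detrends to exact zeros.  Idempotent to numerical
    precision.
    """
    n = len(series)
    if n < 2:
        raise ValueError("need at least 2 samples to detrend")
    k = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), k])
    beta, *_ = np.linalg.lstsq(X, series.values, rcond=None)
    resid = series.values - X @ beta
    return replace(series, values=resid, detrended=True)
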