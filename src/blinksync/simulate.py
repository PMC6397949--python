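"""Synthetic dyad generation with known ground-truth coupling.

Blink trains are mutually exciting point processes: each participant blinks
at a baseline Poisson rate, transiently multiplied after every partner blink
by a raised-cosine kernel centred ``coupling_latency`` seconds after the
partner event.  A refractory period at least as long as a blink keeps events
separable.  Rendering turns event trains into grayscale eye-region frames in
which an eyelid band darkens the region on the way down and back up over the
blink duration; motion energy of such footage is a train of short pulses.

Coupling can be gated by a block schedule to emulate the study conditions:
during live mutual viewing each participant is excited by the partner's
actual blinks; during delayed replay, by the partner's blinks shifted by the
replay delay (what the screen shows); during rest, not at all.

Voxel-pair simulation produces two (volumes x voxels) BOLD-like arrays that
share a latent per-voxel signal (tuned to a target correlation) on top of
task-locked responses and white noise.

All stages are deterministic given the config seed; per-stage and
per-participant substreams are spawned from one master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import BlockSchedule
from .motion import FrameStack

_MAX_SEED = 2**31 - 1


def _substream(seed: int, *keys: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(keys))
    return np.random.default_rng(ss)


@dataclass
class DyadSimConfig:
    """Ground-truth parameters of a simulated dyad.

    Rates are events/min; gains are dimensionless rate multipliers (0 = no
    coupling); latency/width parametrise the raised-cosine excitation
    kernel.  ``blink_duration`` must not exceed ``refractory`` so rendered
    blinks never overlap.
    """

    seed: int = 0
    fs: float = 30.0
    duration: float = 510.0
    baseline_blink_rate: float = 20.0    # events/min, typical adult at rest
    coupling_gain_12: float = 0.0        # influence of participant 1 on 2
    coupling_gain_21: float = 0.0        # influence of participant 2 on 1
    coupling_latency: float = 0.25       # s
    coupling_kernel_width: float = 0.25  # s
    blink_duration: float = 0.3          # s, within the 0.2-0.4 s range
    refractory: float = 0.5              # s

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if min(self.coupling_gain_12, self.coupling_gain_21) < 0:
            raise ValueError("coupling gains must be >= 0")
        if not 0.2 <= self.blink_duration <= 0.4:
            raise ValueError("blink_duration must lie in [0.2, 0.4] s")
        if self.refractory < self.blink_duration:
            raise ValueError("refractory must be >= blink_duration")
        if self.baseline_blink_rate <= 0:
            raise ValueError("baseline rate must be positive")


@dataclass
class SimulatedDyad:
    """Blink onset times (s) of both participants plus the generating truth."""

    events_1: np.ndarray
    events_2: np.ndarray
    truth: DyadSimConfig

    def __post_init__(self) -> None:
        for ev in (self.events_1, self.events_2):
            if len(ev) > 1 and np.any(np.diff(ev) < self.truth.refractory - 1e-9):
                raise ValueError("inter-event gaps below refractory")

    def to_csv(self, path) -> None:
        rows = [(1, t) for t in self.events_1] + [(2, t) for t in self.events_2]
        pd.DataFrame(rows, columns=["participant", "onset_s"]).to_csv(
            path, index=False
        )


def _kernel(dt: np.ndarray, latency: float, width: float) -> np.ndarray:
    """Raised-cosine bump peaking at ``latency``, support width ``width``."""
    u = (dt - latency) / (width / 2.0)
    out = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
    return out


def simulate_coupled_blinks(
    config: DyadSimConfig,
    schedule: BlockSchedule | None = None,
    replay_delay_s: float = 20.0,
) -> SimulatedDyad:
    """Mutually exciting blink trains via Ogata thinning.

    Participant i's hazard is ``r0 * (1 + gain_ji * sum_j K(t - s_j))`` over
    partner events s_j, zero during the refractory period after an own
    blink.  With ``schedule`` given (interpreted on a single-run clock, with
    multi-run schedules unrolled back-to-back), the excitation source is
    gated per condition: partner events during live viewing, partner events
    shifted by ``replay_delay_s`` during replay, none during rest.

    Exact in continuous time: with zero coupling, inter-event gaps are
    refractory + Exponential(r0).
    """
    cfg = config
    r0 = cfg.baseline_blink_rate / 60.0  # events/s
    if 1.0 / r0 <= cfg.refractory:
        raise ValueError(
            "baseline rate too high: mean inter-blink interval "
            f"{1.0 / r0:.3f} s does not exceed the refractory {cfg.refractory} s"
        )
    gains = {0: cfg.coupling_gain_21, 1: cfg.coupling_gain_12}  # onto participant
    # a partner can stack at most this many kernels at once (refractory-bound)
    m_max = int(np.floor(cfg.coupling_kernel_width / cfg.refractory)) + 1
    lam_bar = [r0 * (1.0 + gains[i] * m_max) for i in range(2)]
    total_bar = sum(lam_bar)

    rng = _substream(cfg.seed, 0)
    events: list[list[float]] = [[], []]
    blocked_until = [0.0, 0.0]

    def condition_at(t: float) -> str | None:
        if schedule is None:
            return "LIVE"  # ungated: coupling always live
        run = min(int(t // schedule.run_length), schedule.n_runs - 1)
        return schedule.condition_at(run, t - run * schedule.run_length)

    def hazard(i: int, t: float) -> float:
        if t < blocked_until[i]:
            return 0.0
        exc = 0.0
        if gains[i] > 0:
            cond = condition_at(t)
            partner = np.asarray(events[1 - i])
            if cond == "LIVE":
                src = partner
            elif cond == "REPLAY":
                src = partner + replay_delay_s
            else:
                src = None
            if src is not None and len(src):
                dt = t - src
                lo = cfg.coupling_latency - cfg.coupling_kernel_width / 2
                hi = cfg.coupling_latency + cfg.coupling_kernel_width / 2
                mask = (dt > lo) & (dt < hi)
                if mask.any():
                    exc = float(
                        _kernel(dt[mask], cfg.coupling_latency,
                                cfg.coupling_kernel_width).sum()
                    )
        return r0 * (1.0 + gains[i] * exc)

    t = 0.0
    while True:
        t += rng.exponential(1.0 / total_bar)
        if t >= cfg.duration:
            break
        u = rng.uniform(0.0, total_bar)
        if u < lam_bar[0]:
            i, acc = 0, u
        else:
            i, acc = 1, u - lam_bar[0]
        if acc < hazard(i, t):
            events[i].append(t)
            blocked_until[i] = t + cfg.refractory
    return SimulatedDyad(
        events_1=np.asarray(events[0]),
        events_2=np.asarray(events[1]),
        truth=cfg,
    )


def _eyelid_profile(phase: np.ndarray) -> np.ndarray:
    """Closure fraction over blink phase in [0, 1]: down then up, smooth."""
    return np.sin(np.pi * np.clip(phase, 0.0, 1.0)) ** 2


def render_blink_video(
    events: np.ndarray,
    fs: float,
    frame_shape: tuple[int, int] = (480, 640),
    blink_duration: float = 0.3,
    contrast: float = 30.0,
    duration: float | None = None,
    roi: tuple[int, int, int, int] | None = None,
    background: float = 128.0,
) -> FrameStack:
    """Render blink events as grayscale eye-region footage.

    Frames hold a constant background; during each blink an eyelid band
    sweeps down over the ROI (``(top, left, height, width)``, by default a
    central horizontal strip shaped like an eye region) and back up,
    darkening covered rows by ``contrast`` intensity units.  Frame count is
    round(duration * fs); outside blinks all frames are bit-identical, so
    motion energy is exactly zero there.
    """
    events = np.sort(np.asarray(events, dtype=float))
    if duration is None:
        duration = (events.max() + blink_duration + 1.0) if len(events) else 1.0
    if len(events):
        if events.min() < 0 or events.max() > duration:
            raise ValueError("events outside [0, duration]")
        if np.any(np.diff(events) < blink_duration):
            raise ValueError("overlapping blinks; enforce a refractory period")
    H, W = frame_shape
    if roi is None:
        rh = max(H // 5, 1)
        rw = max((W * 5) // 8, 1)
        roi = ((H - rh) // 2, (W - rw) // 2, rh, rw)
    top, left, rh, rw = roi

    n_frames = int(round(duration * fs))
    frames = np.full((n_frames, H, W), background, dtype=float)
    row_idx = np.arange(rh)
    for ev in events:
        k0 = int(np.ceil(ev * fs - 1e-9))
        k1 = min(int(np.floor((ev + blink_duration) * fs + 1e-9)), n_frames - 1)
        for k in range(max(k0, 0), k1 + 1):
            phase = (k / fs - ev) / blink_duration
            closure = _eyelid_profile(np.array([phase]))[0]
            # fractional coverage of the boundary row keeps the sweep smooth
            frac = np.clip(closure * rh - row_idx, 0.0, 1.0)
            frames[k, top:top + rh, left:left + rw] -= contrast * frac[:, None]
    return FrameStack(frames=frames, fs=fs)


@dataclass
class VoxelPairSim:
    """Paired per-voxel series with known latent coupling."""

    series_a: np.ndarray       # volumes x voxels
    series_b: np.ndarray
    shared_rho: np.ndarray     # per-voxel target latent correlation
    task_design: BlockSchedule | None
    seed: int

    def __post_init__(self) -> None:
        if self.series_a.shape != self.series_b.shape:
            raise ValueError("paired series must share a shape")
        if np.any(np.abs(self.shared_rho) >= 1):
            raise ValueError("shared_rho must lie in (-1, 1)")

    def save(self, prefix) -> None:
        np.savetxt(f"{prefix}_a.csv", self.series_a, delimiter=",")
        np.savetxt(f"{prefix}_b.csv", self.series_b, delimiter=",")
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"seed": self.seed,
                       "shared_rho": np.asarray(self.shared_rho).tolist()}, fh)


def simulate_voxel_pair(
    n_voxels: int,
    n_volumes: int,
    shared_rho,
    task_amp: float = 0.0,
    schedule: BlockSchedule | None = None,
    seed: int = 0,
    tr: float = 1.0,
    rho_by_condition: dict[str, float] | None = None,
) -> VoxelPairSim:
    """Paired voxel series: task response + shared latent + white noise.

    Per voxel, series = task_amp * (condition boxcar convolved with a
    canonical HRF) + loading * latent + noise, with loading =
    sqrt(rho / (1 - rho)) against unit noise so the task-free correlation
    equals ``shared_rho`` in expectation.  ``rho_by_condition`` restricts a
    latent component to volumes inside blocks of one condition (e.g. a
    coupling present only during live viewing).
    """
    from .sync import hrf_regressors  # local import to avoid a cycle

    rho = np.broadcast_to(np.asarray(shared_rho, dtype=float), (n_voxels,)).copy()
    if np.any(np.abs(rho) >= 1):
        raise ValueError("shared_rho must lie in (-1, 1)")
    rng = _substream(seed, 1)
    out = []
    task = np.zeros(n_volumes)
    if schedule is not None and task_amp != 0.0:
        X = hrf_regressors(schedule, n_volumes, tr, conditions=("LIVE", "REPLAY"))
        task = task_amp * X.sum(axis=1)

    def latent_block(rho_vec: np.ndarray, mask: np.ndarray | None):
        lat = rng.standard_normal(n_volumes)
        if mask is not None:
            lat = lat * mask
        loading = np.sqrt(np.abs(rho_vec) / (1.0 - np.abs(rho_vec)))
        sgn = np.sign(rho_vec) + (rho_vec == 0)
        la = np.outer(lat, loading)
        lb = np.outer(lat, loading * sgn)
        return la, lb

    la, lb = latent_block(rho, None)
    if rho_by_condition:
        for cond, r in rho_by_condition.items():
            if schedule is None:
                raise ValueError("rho_by_condition requires a schedule")
            mask = np.zeros(n_volumes, dtype=bool)
            times = np.arange(n_volumes) * tr
            for b in schedule.for_condition(cond):
                t = b.run * schedule.run_length
                mask |= ((times >= t + b.onset) & (times < t + b.end))
            rv = np.broadcast_to(np.asarray(r, dtype=float), (n_voxels,))
            ca, cb = latent_block(rv, mask.astype(float))
            la, lb = la + ca, lb + cb
    a = task[:, None] + la + rng.standard_normal((n_volumes, n_voxels))
    b = task[:, None] + lb + rng.standard_normal((n_volumes, n_voxels))
    return VoxelPairSim(series_a=a, series_b=b, shared_rho=rho,
                        task_design=schedule, seed=seed)
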