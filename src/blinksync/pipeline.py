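"""End-to-end orchestration of synthetic or user-supplied dyad analyses.

``run_behavioral`` sequences the behavioral arm for a cohort of dyads:
simulate (or load) paired blink trains under the block design, render eye
region footage, extract motion energy, count blinks, compute the four
directional sigma-NCR quantities per participant (face-to-face in live,
replay and rest, plus screen-to-face in replay), their rest-baselined
enhancements, and the repeated-measures statistics.  ``run_sync`` sequences
the interbrain-synchronization arm on paired voxel series.  Both emit tidy
data frames, optionally written as CSV alongside a JSON manifest (config
hash, seed, versions) that suffices to replay the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blinks import detect_blinks
from .design import BlockSchedule, make_block_schedule
from .motion import MotionEnergySeries, compute_motion_energy
from .ncr import enhanced_sigma_ncr, participant_sigma_ncr
from .simulate import (DyadSimConfig, SimulatedDyad, render_blink_video,
                       simulate_coupled_blinks, simulate_voxel_pair)
from .stats import paired_t_bonferroni, rm_anova
from .sync import (VoxelSeriesSet, glm_residualize, paired_sync_contrast,
                   split_concat_condition, voxelwise_sync)

logger = logging.getLogger(__name__)

#: the four directional influence quantities, keyed by (condition, source)
SIGMA_NCR_QUANTITIES = ("FF_LIVE", "FF_REPLAY", "SF_REPLAY", "FF_REST")


@dataclass
class RunConfig:
    """Configuration of a full synthetic cohort run."""

    seed: int = 0
    n_dyads: int = 16
    # block design
    n_runs: int = 4
    blocks_per_condition: int = 8
    block_s: float = 20.0
    initial_rest_s: float = 30.0
    analysis_window_s: float = 15.0
    replay_delay_s: float = 20.0
    # dyad generator
    baseline_blink_rate: float = 20.0
    coupling_gain: float = 1.5          # live mutual coupling, both ways
    coupling_latency: float = 0.25
    coupling_kernel_width: float = 0.25
    blink_duration: float = 0.3
    refractory: float = 0.5
    # rendering (small frames keep synthetic cohorts cheap; the pulse shape,
    # not the pixel count, carries the signal)
    frame_shape: tuple[int, int] = (16, 24)
    contrast: float = 30.0
    # detection / NCR
    min_separation_s: float = 0.2
    max_order: int = 10
    n_freqs: int = 513
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_shape"] = list(d["frame_shape"])
        return d

    def manifest(self) -> dict:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return {
            "config": self.to_dict(),
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": self.seed,
            "versions": {"blinksync": __version__, "numpy": np.__version__,
                         "pandas": pd.__version__},
        }


def motion_energy_window(
    events: np.ndarray,
    fs: float,
    t_start: float,
    window_s: float,
    blink_duration: float = 0.3,
    contrast: float = 30.0,
    frame_shape: tuple[int, int] = (16, 24),
) -> MotionEnergySeries:
    """Motion energy of rendered blink footage over [t_start, t_start+window).

    Renders only the frames needed for the window (padded by one blink on
    each side, aligned to the frame grid) so whole-session series never have
    to be materialised; the emitted samples are identical to slicing a
    full-session render.
    """
    from .motion import ROIWindow

    pad = blink_duration + 2.0 / fs
    render_start = np.floor((t_start - pad) * fs) / fs
    render_start = max(render_start, 0.0)
    duration = (t_start - render_start) + window_s + blink_duration
    events = np.asarray(events, dtype=float)
    sel = events[(events >= render_start) & (events < t_start + window_s)]
    stack = render_blink_video(
        sel - render_start, fs, frame_shape=frame_shape,
        blink_duration=blink_duration, contrast=contrast, duration=duration,
    )
    stack.origin_time = render_start
    me = compute_motion_energy(
        stack, ROIWindow(0, 0, frame_shape[0], frame_shape[1])
    )
    i0 = max(int(np.ceil((t_start - me.t0) * fs - 1e-9)), 0)
    n = int(round(window_s * fs))
    return MotionEnergySeries(values=me.values[i0:i0 + n], fs=fs,
                              t0=me.t0 + i0 / fs)


def _session_events(dyad: SimulatedDyad, participant: int) -> np.ndarray:
    return dyad.events_1 if participant == 0 else dyad.events_2


def simulate_dyad(cfg: RunConfig, dyad_index: int
                  ) -> tuple[SimulatedDyad, BlockSchedule]:
    """One dyad's coupled blink trains under its pseudorandomized schedule."""
    schedule = make_block_schedule(
        n_runs=cfg.n_runs, blocks_per_condition=cfg.blocks_per_condition,
        block_s=cfg.block_s, initial_rest_s=cfg.initial_rest_s,
        seed=(cfg.seed * 1_000_003 + dyad_index) % (2**31 - 1),
    )
    sim_cfg = DyadSimConfig(
        seed=(cfg.seed * 7_368_787 + dyad_index) % (2**31 - 1),
        fs=30.0,
        duration=schedule.total_length,
        baseline_blink_rate=cfg.baseline_blink_rate,
        coupling_gain_12=cfg.coupling_gain,
        coupling_gain_21=cfg.coupling_gain,
        coupling_latency=cfg.coupling_latency,
        coupling_kernel_width=cfg.coupling_kernel_width,
        blink_duration=cfg.blink_duration,
        refractory=cfg.refractory,
    )
    dyad = simulate_coupled_blinks(sim_cfg, schedule=schedule,
                                   replay_delay_s=cfg.replay_delay_s)
    return dyad, schedule


def run_behavioral(config: RunConfig) -> dict:
    """Behavioral arm over a synthetic cohort; returns the result bundle.

    Bundle keys: ``blink_counts``, ``sigma_ncr``, ``enhancement`` (tidy
    frames), ``per_block`` (per-block sigma-NCR), ``anova_sigma_ncr``,
    ``anova_enhancement``, ``anova_blinks``, ``posthoc_sigma_ncr``,
    ``manifest``.  Dyads whose analysis fails are logged and skipped.
    """
    cfg = config
    count_rows, ncr_rows, block_rows = [], [], []
    kw = dict(window_s=cfg.analysis_window_s, blink_duration=cfg.blink_duration,
              contrast=cfg.contrast, frame_shape=cfg.frame_shape)
    for d in range(cfg.n_dyads):
        try:
            dyad, schedule = simulate_dyad(cfg, d)
            fs = dyad.truth.fs
            # each participant's own block series, rendered once and shared
            # between blink counting and every face-to-face quantity
            own: dict[tuple[int, str], list[MotionEnergySeries]] = {}
            for p in (0, 1):
                ev = _session_events(dyad, p)
                for cond in ("LIVE", "REPLAY", "REST"):
                    own[(p, cond)] = [
                        motion_energy_window(
                            ev, fs,
                            t_start=(b.run * schedule.run_length + b.end
                                     - cfg.analysis_window_s),
                            **kw)
                        for b in schedule.for_condition(cond)
                    ]
            for p in (0, 1):
                pid = f"d{d:02d}p{p + 1}"
                for cond in ("LIVE", "REPLAY", "REST"):
                    counts = [
                        len(detect_blinks(blk, cfg.min_separation_s))
                        for blk in own[(p, cond)]
                    ]
                    count_rows.append((d, pid, cond, float(np.mean(counts))))
                for quantity in SIGMA_NCR_QUANTITIES:
                    tag, cond = quantity.split("_")
                    if tag == "SF":  # the replay screen: partner, delayed
                        ev_s = _session_events(dyad, 1 - p)
                        pairs = []
                        for k, b in enumerate(schedule.for_condition(cond)):
                            t_start = (b.run * schedule.run_length + b.end
                                       - cfg.analysis_window_s)
                            y = motion_energy_window(
                                ev_s, fs,
                                t_start=t_start - cfg.replay_delay_s, **kw)
                            y.t0 += cfg.replay_delay_s
                            pairs.append((own[(p, cond)][k], y))
                    else:
                        pairs = list(zip(own[(p, cond)], own[(1 - p, cond)]))
                    mean, table = participant_sigma_ncr(
                        pairs, max_order=cfg.max_order, n_freqs=cfg.n_freqs
                    )
                    ncr_rows.append((d, pid, quantity, mean))
                    for _, row in table.iterrows():
                        block_rows.append(
                            (d, pid, quantity, int(row["block"]),
                             int(row["order"]), row["sigma_ncr"],
                             row["residual_corr"])
                        )
        except Exception:
            logger.exception("dyad %d failed; continuing", d)

    blink_counts = pd.DataFrame(
        count_rows, columns=["dyad", "participant", "condition", "value"])
    sigma_ncr = pd.DataFrame(
        ncr_rows, columns=["dyad", "participant", "condition", "value"])
    per_block = pd.DataFrame(
        block_rows, columns=["dyad", "participant", "condition", "block",
                             "order", "sigma_ncr", "residual_corr"])

    wide = sigma_ncr.pivot_table(index="participant", columns="condition",
                                 values="value")
    enh_rows = []
    for pid, row in wide.iterrows():
        for q in ("FF_LIVE", "FF_REPLAY", "SF_REPLAY"):
            enh_rows.append((pid, q,
                             enhanced_sigma_ncr(row[q], row["FF_REST"])))
    enhancement = pd.DataFrame(
        enh_rows, columns=["participant", "condition", "value"])

    bundle = {
        "blink_counts": blink_counts,
        "sigma_ncr": sigma_ncr,
        "per_block": per_block,
        "enhancement": enhancement,
        "anova_blinks": rm_anova(blink_counts),
        "anova_sigma_ncr": rm_anova(sigma_ncr),
        "anova_enhancement": rm_anova(enhancement),
        "posthoc_sigma_ncr": paired_t_bonferroni(
            sigma_ncr,
            [("FF_LIVE", "FF_REPLAY"), ("FF_LIVE", "FF_REST"),
             ("FF_LIVE", "SF_REPLAY"), ("FF_REPLAY", "FF_REST"),
             ("FF_REPLAY", "SF_REPLAY"), ("FF_REST", "SF_REPLAY")],
        ),
        "manifest": cfg.manifest(),
    }
    if cfg.out_dir:
        _write_bundle(bundle, cfg.out_dir)
    return bundle


@dataclass
class SyncConfig:
    """Configuration of the synthetic interbrain-synchronization arm."""

    seed: int = 0
    n_dyads: int = 8
    n_voxels: int = 200
    tr: float = 1.0
    n_runs: int = 4
    blocks_per_condition: int = 8
    block_s: float = 20.0
    initial_rest_s: float = 30.0
    shared_rho: float = 0.0             # always-on latent coupling
    rho_live: float = 0.0               # extra coupling during LIVE only
    live_voxels: int | None = None      # restrict rho_live to the first k voxels
    task_amp: float = 1.0
    highpass_s: float = 128.0
    drop_initial: int = 10
    out_dir: str | None = None

    def manifest(self) -> dict:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return {"config": dataclasses.asdict(self),
                "config_sha256": hashlib.sha256(blob).hexdigest(),
                "seed": self.seed,
                "versions": {"blinksync": __version__,
                             "numpy": np.__version__}}


def run_sync(config: SyncConfig) -> dict:
    """Synchronization arm over a synthetic cohort; returns the bundle.

    Bundle keys: ``z_live``, ``z_replay`` (lists of per-dyad SyncMaps),
    ``contrast`` (per-voxel paired-t table), ``manifest``.
    """
    cfg = config
    schedule = make_block_schedule(
        n_runs=cfg.n_runs, blocks_per_condition=cfg.blocks_per_condition,
        block_s=cfg.block_s, initial_rest_s=cfg.initial_rest_s, seed=cfg.seed,
    )
    n_volumes = int(round(schedule.total_length / cfg.tr))
    z_live, z_replay = [], []
    for d in range(cfg.n_dyads):
        rho_by_condition = None
        if cfg.rho_live:
            k = cfg.live_voxels or cfg.n_voxels
            rv = np.zeros(cfg.n_voxels)
            rv[:k] = cfg.rho_live
            rho_by_condition = {"LIVE": rv}
        sim = simulate_voxel_pair(
            cfg.n_voxels, n_volumes, cfg.shared_rho, task_amp=cfg.task_amp,
            schedule=schedule, seed=(cfg.seed * 52_9 + d) % (2**31 - 1),
            tr=cfg.tr, rho_by_condition=rho_by_condition,
        )
        maps = {}
        resid = {}
        for label, arr in (("a", sim.series_a), ("b", sim.series_b)):
            vs = VoxelSeriesSet.from_array(arr, cfg.tr, cfg.n_runs)
            resid[label] = glm_residualize(
                vs, schedule, highpass_s=cfg.highpass_s,
                drop_initial=cfg.drop_initial,
            )
        for cond, sink in (("LIVE", z_live), ("REPLAY", z_replay)):
            ca = split_concat_condition(resid["a"], schedule, cond)
            cb = split_concat_condition(resid["b"], schedule, cond)
            sink.append(voxelwise_sync(ca, cb, condition=cond))
    contrast = paired_sync_contrast(z_live, z_replay)
    bundle = {"z_live": z_live, "z_replay": z_replay, "contrast": contrast,
              "manifest": cfg.manifest()}
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        contrast.to_csv(out / "sync_contrast.csv", index=False)
        zl = pd.concat([m.to_frame().assign(dyad=i)
                        for i, m in enumerate(z_live)])
        zr = pd.concat([m.to_frame().assign(dyad=i)
                        for i, m in enumerate(z_replay)])
        zl.to_csv(out / "z_live.csv", index=False)
        zr.to_csv(out / "z_replay.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle["manifest"], fh, indent=2)
    return bundle


def _write_bundle(bundle: dict, out_dir: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key in ("blink_counts", "sigma_ncr", "per_block", "enhancement",
                "posthoc_sigma_ncr"):
        bundle[key].to_csv(out / f"{key}.csv", index=False)
    stats_rows = []
    for key in ("anova_blinks", "anova_sigma_ncr", "anova_enhancement"):
        for res in bundle[key]:
            stats_rows.append({
                "table": key, "effect": res.effect, "F": res.F,
                "df_num": res.df_num, "df_den": res.df_den, "p": res.p,
                "generalized_eta2": res.generalized_eta2,
            })
    pd.DataFrame(stats_rows).to_csv(out / "anova.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2)
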