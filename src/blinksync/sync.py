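"""Interbrain synchronization between homologous voxels of a dyad.

The pipeline mirrors the in-house portion of a hyperscanning fMRI
synchronization analysis: per run, drop the first volumes acquired before
magnetization reaches steady state, regress out task-locked responses
(condition boxcars convolved with a canonical double-gamma HRF), run
intercepts and slow drifts (discrete-cosine high-pass basis), then split the
residual series by condition, concatenate across blocks and runs, correlate
partner voxels that share an identifier (standing in for identical template
coordinates), and Fisher z-transform the per-voxel correlations.  Condition
differences across dyads are tested with a voxel-wise paired t map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import BlockSchedule

logger = logging.getLogger(__name__)

_R_CLAMP = 1.0 - 1e-12


@dataclass
class VoxelSeriesSet:
    """(volumes x voxels) series with run boundaries and shared voxel ids."""

    data: np.ndarray
    tr: float
    run_boundaries: np.ndarray      # start index of each run
    voxel_ids: np.ndarray
    volume_times: np.ndarray | None = None   # s within run, per volume

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.run_boundaries = np.asarray(self.run_boundaries, dtype=int)
        self.voxel_ids = np.asarray(self.voxel_ids)
        if self.data.ndim != 2:
            raise ValueError("data must be (volumes, voxels)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite voxel values")
        if self.data.shape[1] != len(self.voxel_ids):
            raise ValueError("voxel_ids must match data columns")
        lengths = np.diff(np.append(self.run_boundaries, self.data.shape[0]))
        if len(set(lengths.tolist())) > 1:
            raise ValueError("runs must have equal lengths")
        if self.volume_times is None:
            per_run = lengths[0]
            self.volume_times = np.tile(np.arange(per_run) * self.tr,
                                        len(self.run_boundaries))

    @property
    def n_runs(self) -> int:
        return len(self.run_boundaries)

    @property
    def volumes_per_run(self) -> int:
        return self.data.shape[0] // self.n_runs

    def run_slice(self, r: int) -> slice:
        start = self.run_boundaries[r]
        end = (self.run_boundaries[r + 1] if r + 1 < self.n_runs
               else self.data.shape[0])
        return slice(start, end)

    @classmethod
    def from_array(cls, data: np.ndarray, tr: float, n_runs: int,
                   voxel_ids=None) -> "VoxelSeriesSet":
        data = np.asarray(data, dtype=float)
        per_run = data.shape[0] // n_runs
        if per_run * n_runs != data.shape[0]:
            raise ValueError("volumes not divisible by n_runs")
        ids = (np.arange(data.shape[1]) if voxel_ids is None
               else np.asarray(voxel_ids))
        return cls(data=data, tr=tr,
                   run_boundaries=np.arange(n_runs) * per_run, voxel_ids=ids)

    @classmethod
    def from_nifti(cls, paths: list, tr: float, voxel_ids=None) -> "VoxelSeriesSet":
        """Stack one 4-D NIfTI per run into (volumes, voxels)."""
        import nibabel as nib

        runs = []
        for p in paths:
            img = nib.load(str(p))
            vol = np.asarray(img.dataobj, dtype=float)
            runs.append(vol.reshape(-1, vol.shape[-1]).T)
        data = np.vstack(runs)
        return cls.from_array(data, tr, n_runs=len(paths), voxel_ids=voxel_ids)


@dataclass
class SyncMap:
    """Per-voxel interbrain correlation and Fisher z for one condition."""

    voxel_ids: np.ndarray
    r: np.ndarray
    z: np.ndarray
    condition: str
    n_volumes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"voxel_id": self.voxel_ids, "r": self.r,
                             "z": self.z})


def double_gamma_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak-normalised to 1)."""
    t = np.asarray(t, dtype=float)
    h = sps.gamma.pdf(t, peak) - ratio * sps.gamma.pdf(t, undershoot)
    peak_val = h.max()
    return h / peak_val if peak_val > 0 else h


def hrf_regressors(
    schedule: BlockSchedule,
    n_volumes: int,
    tr: float,
    conditions: tuple[str, ...] = ("LIVE", "REPLAY"),
    oversample: int = 10,
    run_times: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Condition boxcars convolved with the canonical HRF, one column each.

    ``n_volumes`` covers the whole session (runs back-to-back); convolution
    is performed per run so responses never bleed across run boundaries.
    ``run_times`` overrides the per-run acquisition times (s within run, one
    array per run; by default volume k is acquired at k * tr).
    """
    per_run = n_volumes // schedule.n_runs
    if run_times is None:
        run_times = [np.arange(per_run) * tr for _ in range(schedule.n_runs)]
    dt = tr / oversample
    hrf_t = np.arange(0, 32.0, dt)
    hrf = double_gamma_hrf(hrf_t)
    X = np.zeros((sum(len(t) for t in run_times), len(conditions)))
    n_fine = int(round(schedule.run_length / dt))
    fine_t = np.arange(n_fine) * dt
    for ci, cond in enumerate(conditions):
        row0 = 0
        for r in range(schedule.n_runs):
            box = np.zeros(n_fine)
            for b in schedule.for_condition(cond):
                if b.run != r:
                    continue
                box[(fine_t >= b.onset) & (fine_t < b.end)] = 1.0
            conv = np.convolve(box, hrf)[:n_fine]
            sample_idx = np.round(run_times[r] / dt).astype(int)
            sample_idx = np.clip(sample_idx, 0, n_fine - 1)
            X[row0:row0 + len(run_times[r]), ci] = conv[sample_idx]
            row0 += len(run_times[r])
    return X


def dct_basis(n: int, tr: float, highpass_s: float) -> np.ndarray:
    """Discrete-cosine drift basis with periods above ``highpass_s`` seconds."""
    order = int(np.floor(2.0 * n * tr / highpass_s))
    k = np.arange(n)
    cols = [np.cos(np.pi * (2 * k + 1) * j / (2.0 * n)) for j in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def glm_residualize(
    series: VoxelSeriesSet,
    schedule: BlockSchedule,
    highpass_s: float = 128.0,
    drop_initial: int = 10,
    conditions: tuple[str, ...] = ("LIVE", "REPLAY"),
) -> VoxelSeriesSet:
    """Remove task-locked responses and slow drifts from every voxel.

    Per run the first ``drop_initial`` volumes are discarded, then a GLM with
    per-condition HRF-convolved boxcars (REST serving as the implicit
    baseline), a run intercept and a discrete-cosine high-pass basis
    (cutoff ``highpass_s``) is projected out.  Returns the residual set.
    """
    if schedule.n_runs != series.n_runs:
        raise ValueError("schedule and series disagree on the number of runs")
    kept_times = [series.volume_times[series.run_slice(r)][drop_initial:]
                  for r in range(series.n_runs)]
    # task regressors sampled at the actual acquisition times, so applying
    # the projection twice is a no-op
    task = hrf_regressors(schedule, series.data.shape[0], series.tr,
                          conditions, run_times=kept_times)

    out_runs, out_times = [], []
    row0 = 0
    for r in range(series.n_runs):
        sl = series.run_slice(r)
        y = series.data[sl][drop_initial:]
        n_kept = y.shape[0]
        Xr = task[row0:row0 + n_kept]
        row0 += n_kept
        drift = dct_basis(n_kept, series.tr, highpass_s)
        X = np.column_stack([Xr, np.ones(n_kept), drift])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            names = np.array(
                [f"task:{c}" for c in conditions] + ["intercept"]
                + [f"dct:{j}" for j in range(drift.shape[1])]
            )
            # pivoted QR: columns pivoted past the numerical rank are the
            # linearly dependent ones
            from scipy.linalg import qr as _qr

            _, _, piv = _qr(X, mode="economic", pivoting=True)
            offending = names[piv[rank:]]
            raise ValueError(
                f"collinear design in run {r}: offending columns "
                f"{offending.tolist()}"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out_runs.append(y - X @ beta)
        out_times.append(kept_times[r])

    data = np.vstack(out_runs)
    n_per = out_runs[0].shape[0]
    return VoxelSeriesSet(
        data=data, tr=series.tr,
        run_boundaries=np.arange(series.n_runs) * n_per,
        voxel_ids=series.voxel_ids,
        volume_times=np.concatenate(out_times),
    )


def split_concat_condition(
    series: VoxelSeriesSet,
    schedule: BlockSchedule,
    condition: str,
) -> VoxelSeriesSet:
    """Concatenate the volumes acquired during one condition's blocks.

    A volume belongs to a block when its within-run acquisition time falls in
    the half-open interval [onset, onset + duration).  Order is temporal:
    runs, then blocks, then volumes.
    """
    keep: list[int] = []
    for r in range(series.n_runs):
        sl = series.run_slice(r)
        idx = np.arange(sl.start, sl.stop)
        times = series.volume_times[sl.start:sl.stop]
        for b in schedule.for_condition(condition):
            if b.run != r:
                continue
            sel = idx[(times >= b.onset) & (times < b.end)]
            keep.extend(sel.tolist())
    if not keep:
        raise ValueError(f"no volumes fall inside {condition} blocks")
    data = series.data[keep]
    return VoxelSeriesSet(
        data=data, tr=series.tr, run_boundaries=np.array([0]),
        voxel_ids=series.voxel_ids,
        volume_times=np.arange(len(keep)) * series.tr,
    )


def voxelwise_sync(a: VoxelSeriesSet, b: VoxelSeriesSet,
                   condition: str = "") -> SyncMap:
    """Pearson r between same-id voxels of two participants, Fisher z-mapped.

    r is clamped to +/-(1 - 1e-12) before atanh; zero-variance voxels get
    z = 0 with a logged warning.
    """
    if a.data.shape != b.data.shape:
        raise ValueError("participants' series differ in shape")
    if not np.array_equal(a.voxel_ids, b.voxel_ids):
        raise ValueError("voxel ids do not match")
    xa = a.data - a.data.mean(axis=0)
    xb = b.data - b.data.mean(axis=0)
    na = np.sqrt((xa ** 2).sum(axis=0))
    nb = np.sqrt((xb ** 2).sum(axis=0))
    bad = (na == 0) | (nb == 0)
    if bad.any():
        logger.warning("%d zero-variance voxels; their z set to 0", bad.sum())
    denom = np.where(bad, 1.0, na * nb)
    r = (xa * xb).sum(axis=0) / denom
    r = np.where(bad, 0.0, np.clip(r, -_R_CLAMP, _R_CLAMP))
    return SyncMap(voxel_ids=a.voxel_ids.copy(), r=r, z=np.arctanh(r),
                   condition=condition, n_volumes=a.data.shape[0])


def paired_sync_contrast(
    z_maps_a: list[SyncMap], z_maps_b: list[SyncMap]
) -> pd.DataFrame:
    """Voxel-wise paired t between two conditions' z-maps across dyads.

    One map per dyad per condition, matched by list position.  Returns a
    per-voxel table of t and uncorrected p; cluster-level family-wise
    inference is out of scope.
    """
    if len(z_maps_a) != len(z_maps_b):
        raise ValueError("need one map per dyad in each condition")
    if len(z_maps_a) < 3:
        raise ValueError("need at least 3 dyads for a paired t map")
    ids = z_maps_a[0].voxel_ids
    Za = np.stack([m.z for m in z_maps_a])
    Zb = np.stack([m.z for m in z_maps_b])
    t, p = sps.ttest_rel(Za, Zb, axis=0)
    # voxels with identical maps in both conditions test as "no difference"
    degenerate = np.isnan(t) & np.all(Za - Zb == (Za - Zb)[0], axis=0) \
        & ((Za - Zb)[0] == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame({"voxel_id": ids, "t": t, "p_uncorrected": p})


def save_map_csv(map_: SyncMap, path) -> None:
    map_.to_frame().to_csv(path, index=False)
    with open(str(path) + ".json", "w") as fh:
        json.dump({"condition": map_.condition,
                   "n_volumes": map_.n_volumes}, fh)


def save_map_nifti(map_: SyncMap, shape3d: tuple[int, int, int], path) -> None:
    """Write the z map back onto a 3-D grid (voxel ids = flat indices)."""
    import nibabel as nib

    vol = np.zeros(int(np.prod(shape3d)))
    vol[np.asarray(map_.voxel_ids, dtype=int)] = map_.z
    nib.save(nib.Nifti1Image(vol.reshape(shape3d), np.eye(4)), str(path))
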