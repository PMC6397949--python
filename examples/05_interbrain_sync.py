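"""Interbrain synchronization on synthetic paired voxel series.

Each dyad gets paired (volumes x voxels) series sharing a latent signal in
the first 10 voxels during LIVE blocks only, plus a common task response.
The pipeline residualizes the task, splits and concatenates volumes per
condition (640 each for live and replay under the canonical design),
correlates homologous voxels, Fisher-transforms, and contrasts conditions
with a voxel-wise paired t map — which should single out the planted voxels.
"""

import logging

logging.disable(logging.WARNING)

import numpy as np

from blinksync import SyncConfig, run_sync

config = SyncConfig(seed=9, n_dyads=6, n_voxels=50, rho_live=0.6,
                    live_voxels=10, task_amp=2.0)
bundle = run_sync(config)

z_live = np.stack([m.z for m in bundle["z_live"]])
z_replay = np.stack([m.z for m in bundle["z_replay"]])
print(f"volumes per condition map: {bundle['z_live'][0].n_volumes}")
print(f"mean z, planted voxels (0-9):   live {z_live[:, :10].mean():.3f}  "
      f"replay {z_replay[:, :10].mean():.3f}")
print(f"mean z, remaining voxels:       live {z_live[:, 10:].mean():.3f}  "
      f"replay {z_replay[:, 10:].mean():.3f}")

contrast = bundle["contrast"]
top = contrast.nlargest(10, "t")["voxel_id"].to_numpy()
hits = len(np.intersect1d(top, np.arange(10)))
print(f"top-10 |t| voxels in the live-minus-replay map: "
      f"{sorted(int(v) for v in top)}")
print(f"{hits}/10 are the planted voxels — live-specific shared signal "
      "survives task residualization, task-locked correlation does not")
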