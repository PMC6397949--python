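"""Block-design schedules for dyadic hyperscanning runs.

A run is a sequence of non-overlapping condition blocks (LIVE, REPLAY,
REST).  The canonical run opens with a 30 s REST baseline followed by 24
pseudorandomly ordered 20 s blocks — eight per condition — for a total of
510 s.  The 1 s blank that separates consecutive face presentations is
counted inside the preceding block's final second, so block onsets tile the
run without gaps and the run-length arithmetic stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("LIVE", "REPLAY", "REST")


@dataclass(frozen=True)
class Block:
    condition: str
    onset: float       # s, relative to run start
    duration: float    # s
    run: int           # 0-based run index

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class BlockSchedule:
    """Ordered, non-overlapping condition blocks across one or more runs."""

    blocks: list[Block]
    run_length: float
    n_runs: int

    def __post_init__(self) -> None:
        by_run: dict[int, list[Block]] = {}
        for b in self.blocks:
            if b.condition not in CONDITIONS:
                raise ValueError(f"unknown condition {b.condition!r}")
            if b.end > self.run_length + 1e-9:
                raise ValueError(
                    f"block {b} extends past run_length {self.run_length}"
                )
            by_run.setdefault(b.run, []).append(b)
        for run, blks in by_run.items():
            blks = sorted(blks, key=lambda b: b.onset)
            for a, b in zip(blks, blks[1:]):
                if b.onset < a.end - 1e-9:
                    raise ValueError(f"overlapping blocks in run {run}: {a}, {b}")

    def for_condition(self, condition: str) -> list[Block]:
        """Blocks of one condition, ordered by (run, onset)."""
        return sorted(
            (b for b in self.blocks if b.condition == condition),
            key=lambda b: (b.run, b.onset),
        )

    def condition_at(self, run: int, t: float) -> str | None:
        """Condition whose half-open interval [onset, end) contains time t."""
        for b in self.blocks:
            if b.run == run and b.onset <= t < b.end:
                return b.condition
        return None

    @property
    def total_length(self) -> float:
        return self.n_runs * self.run_length

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b.run, b.condition, b.onset, b.duration) for b in self.blocks],
            columns=["run", "condition", "onset_s", "duration_s"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def make_block_schedule(
    n_runs: int = 4,
    blocks_per_condition: int = 8,
    block_s: float = 20.0,
    initial_rest_s: float = 30.0,
    gap_s: float = 0.0,
    seed: int = 0,
    expected_run_length_s: float | None = None,
) -> BlockSchedule:
    """Build the canonical pseudorandomized block schedule.

    Each run holds ``blocks_per_condition`` blocks of each of LIVE, REPLAY
    and REST (beyond the initial REST baseline), in a pseudorandom order
    that is deterministic given ``seed``.  ``gap_s`` inserts an explicit
    silent gap after every block; the canonical design uses 0 because the
    1 s blank lives inside the block.

    Defaults give run_length = 30 + 24*20 = 510 s.

    Raises ``ValueError`` if ``expected_run_length_s`` is supplied and the
    computed run length disagrees with it.
    """
    if min(n_runs, blocks_per_condition + 1, block_s, initial_rest_s) <= 0:
        raise ValueError("n_runs, block_s and initial_rest_s must be positive; "
                         "blocks_per_condition must be >= 0")
    if gap_s < 0:
        raise ValueError("gap_s must be >= 0")

    n_blocks = 3 * blocks_per_condition
    run_length = initial_rest_s + n_blocks * (block_s + gap_s)
    if expected_run_length_s is not None and not np.isclose(
        run_length, expected_run_length_s
    ):
        raise ValueError(
            f"computed run length {run_length} s disagrees with expected "
            f"{expected_run_length_s} s"
        )

    rng = np.random.default_rng(seed)
    blocks: list[Block] = []
    for run in range(n_runs):
        blocks.append(Block("REST", 0.0, initial_rest_s, run))
        order = np.repeat(np.arange(3), blocks_per_condition)
        rng.shuffle(order)
        t = initial_rest_s
        for idx in order:
            blocks.append(Block(CONDITIONS[idx], t, block_s, run))
            t += block_s + gap_s
    return BlockSchedule(blocks=blocks, run_length=run_length, n_runs=n_runs)
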