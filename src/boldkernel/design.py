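"""Block task designs (alternating rest / movement periods).

The motor paradigm is a block design: fixed-length rest blocks interleaved
with fixed-length movement blocks, always starting with rest.  The design is
shared by the ECoG analysis (window segmentation) and the fMRI analysis
(boxcar regressor construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MOVEMENT = "movement"
REST = "rest"
CONDITIONS = (REST, MOVEMENT)

__all__ = ["TaskDesign", "make_design", "MOVEMENT", "REST", "CONDITIONS"]


@dataclass(frozen=True)
class TaskDesign:
    """A sorted, contiguous, non-overlapping sequence of condition blocks.

    Parameters
    ----------
    onsets
        Block onset times in seconds.
    durations
        Block durations in seconds (all > 0).
    conditions
        One of ``"rest"`` / ``"movement"`` per block.
    """

    onsets: tuple[float, ...]
    durations: tuple[float, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        if not (len(onsets) == len(durations) == len(self.conditions)):
            raise ValueError("onsets, durations and conditions must have equal length")
        if len(onsets) == 0:
            raise ValueError("design must contain at least one block")
        if np.any(durations <= 0):
            raise ValueError("all block durations must be positive")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("block onsets must be strictly increasing")
        # contiguity: each block starts where the previous one ends
        ends = onsets[:-1] + durations[:-1]
        if not np.allclose(ends, onsets[1:], atol=1e-9):
            raise ValueError("blocks must be contiguous (no gaps or overlaps)")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}; expected one of {CONDITIONS}")

    @property
    def n_blocks(self) -> int:
        return len(self.onsets)

    @property
    def total_duration(self) -> float:
        return float(self.onsets[-1] + self.durations[-1])

    def blocks(self, condition: str) -> list[tuple[float, float]]:
        """Return ``(onset, duration)`` pairs for one condition."""
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return [
            (float(o), float(d))
            for o, d, c in zip(self.onsets, self.durations, self.conditions)
            if c == condition
        ]

    def movement_indicator(self, times: np.ndarray) -> np.ndarray:
        """Boxcar sampled at ``times``: 1.0 during movement blocks, else 0.0."""
        times = np.asarray(times, dtype=float)
        out = np.zeros_like(times)
        for onset, dur in self.blocks(MOVEMENT):
            out[(times >= onset) & (times < onset + dur)] = 1.0
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"onset": self.onsets, "duration": self.durations, "trial_type": self.conditions}
        )


def make_design(
    n_movement_blocks: int, n_rest_blocks: int, block_s: float = 30.0
) -> TaskDesign:
    """Build the alternating rest/movement block design, starting with rest.

    ``n_rest_blocks`` must equal ``n_movement_blocks`` or exceed it by one
    (rest-first alternation admits no other layout).

    Examples
    --------
    >>> make_design(4, 5, 30).total_duration
    270.0
    >>> make_design(5, 5, 30).total_duration
    300.0
    """
    if n_movement_blocks < 1 or n_rest_blocks < 1:
        raise ValueError("block counts must be >= 1")
    if block_s <= 0:
        raise ValueError("block duration must be positive")
    if n_rest_blocks not in (n_movement_blocks, n_movement_blocks + 1):
        raise ValueError(
            "rest-first alternation requires n_rest_blocks in "
            "{n_movement_blocks, n_movement_blocks + 1}"
        )
    conditions: list[str] = []
    n_r, n_m = n_rest_blocks, n_movement_blocks
    while n_r or n_m:
        if n_r:
            conditions.append(REST)
            n_r -= 1
        if n_m:
            conditions.append(MOVEMENT)
            n_m -= 1
    n = len(conditions)
    onsets = tuple(i * float(block_s) for i in range(n))
    durations = (float(block_s),) * n
    return TaskDesign(onsets, durations, tuple(conditions))
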