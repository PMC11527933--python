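"""Dynamic-PET frame schedules.

A schedule is an ordered, contiguous list of acquisition frames starting at
injection.  Times are minutes post injection internally; frame durations are
specified in seconds, the convention used for list-mode re-binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "default_schedule", "LITERAL_REBINNING_S"]

#: the acquisition re-binning as printed: 1x15 s, 3x5 s, 3x10 s, 2x30 s,
#: 3x60 s, 2x150 s, 2x300 s, 7x300 s (sums to 55 min)
LITERAL_REBINNING_S: tuple[int, ...] = (
    (15,) + (5,) * 3 + (10,) * 3 + (30,) * 2 + (60,) * 3 + (150,) * 2 + (300,) * 2 + (300,) * 7
)

#: the same list with the final block widened to 7x600 s so the schedule
#: covers the full 90-min acquisition
EXTENDED_REBINNING_S: tuple[int, ...] = LITERAL_REBINNING_S[:-7] + (600,) * 7


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames.

    Attributes
    ----------
    frame_durations_s : ndarray
        Frame durations in seconds, all positive.
    frame_starts_min : ndarray
        Frame start times in minutes; first frame starts at injection (0)
        and each frame begins where the previous one ends.
    """

    frame_durations_s: np.ndarray
    frame_starts_min: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        durations = np.asarray(self.frame_durations_s, dtype=float)
        if durations.ndim != 1 or durations.size == 0:
            raise ValueError("schedule needs at least one frame")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be positive")
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]]) / 60.0
        if self.frame_starts_min is not None:
            given = np.asarray(self.frame_starts_min, dtype=float)
            if not np.allclose(given, starts, atol=1e-9):
                raise ValueError("frames must be contiguous from t=0")
        object.__setattr__(self, "frame_durations_s", durations)
        object.__setattr__(self, "frame_starts_min", starts)

    @property
    def n_frames(self) -> int:
        return int(self.frame_durations_s.size)

    @property
    def frame_durations_min(self) -> np.ndarray:
        return self.frame_durations_s / 60.0

    @property
    def midpoints_min(self) -> np.ndarray:
        """Frame midpoints in minutes, the time coordinate used for fitting."""
        return self.frame_starts_min + self.frame_durations_min / 2.0

    @property
    def frame_ends_min(self) -> np.ndarray:
        return self.frame_starts_min + self.frame_durations_min

    @property
    def boundaries_min(self) -> np.ndarray:
        """The n_frames + 1 frame-boundary times, 0 ... total duration."""
        return np.concatenate([self.frame_starts_min, [self.total_duration_min]])

    @property
    def total_duration_s(self) -> float:
        return float(self.frame_durations_s.sum())

    @property
    def total_duration_min(self) -> float:
        return self.total_duration_s / 60.0


def default_schedule(extended: bool = True) -> FrameSchedule:
    """The acquisition re-binning used throughout.

    With ``extended=True`` (default) the final seven frames are 600 s each so
    the schedule spans the full 90-min acquisition; with ``extended=False``
    the literal 55-min re-binning list is returned.
    """
    durations = EXTENDED_REBINNING_S if extended else LITERAL_REBINNING_S
    return FrameSchedule(np.array(durations, dtype=float))
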