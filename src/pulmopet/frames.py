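"""Dynamic-PET frame timing.

The acquisition protocol is a list of (count, duration) blocks; the default
is the 24-frame, 280 s lung protocol (14x5 s, 3x10 s, 3x20 s, 4x30 s) with
acquisition starting 30 s after the start of the tracer bolus.  All times
are seconds.  Frame values are understood as time-averages of the
continuous signal over the frame, since PET frames integrate counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["FrameSchedule", "make_frame_schedule", "PAPER_PROTOCOL"]

#: Default acquisition protocol: (frame count, frame duration in s) blocks.
PAPER_PROTOCOL: tuple[tuple[int, float], ...] = ((14, 5.0), (3, 10.0), (3, 20.0), (4, 30.0))


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame durations plus an acquisition start offset.

    `start_s` is the delay from tracer-injection start to acquisition
    start; frame start/mid/end times are reported on the injection clock
    (i.e. offset by `start_s`).
    """

    durations_s: tuple[float, ...]
    start_s: float = 30.0

    def __post_init__(self) -> None:
        durations = tuple(float(d) for d in self.durations_s)
        if len(durations) == 0:
            raise ValueError("schedule must contain at least one frame")
        if any(d <= 0 for d in durations):
            raise ValueError("all frame durations must be positive")
        if self.start_s < 0:
            raise ValueError("start offset must be non-negative")
        object.__setattr__(self, "durations_s", durations)
        object.__setattr__(self, "start_s", float(self.start_s))

    @property
    def n_frames(self) -> int:
        return len(self.durations_s)

    @property
    def total_duration_s(self) -> float:
        return float(sum(self.durations_s))

    @property
    def start_times_s(self) -> np.ndarray:
        edges = np.concatenate([[0.0], np.cumsum(self.durations_s)[:-1]])
        return edges + self.start_s

    @property
    def end_times_s(self) -> np.ndarray:
        return np.cumsum(self.durations_s) + self.start_s

    @property
    def mid_times_s(self) -> np.ndarray:
        return (self.start_times_s + self.end_times_s) / 2.0

    @property
    def scan_mid_times_s(self) -> np.ndarray:
        """Frame mid-times on the scan clock (t = 0 at acquisition start).

        TACs are anchored on this clock so the 1 s analysis grid 0...280
        covers the whole scan and the zero-concentration boundary
        condition refers to scan start.
        """
        return self.mid_times_s - self.start_s

    def to_dict(self) -> dict:
        return {"frame_durations_s": list(self.durations_s), "start_s": self.start_s}

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(tuple(d["frame_durations_s"]), float(d.get("start_s", 0.0)))


def make_frame_schedule(
    spec: Sequence[tuple[int, float]] = PAPER_PROTOCOL,
    start_s: float = 30.0,
) -> FrameSchedule:
    """Build a :class:`FrameSchedule` from (count, duration) blocks.

    The default spec is the 24-frame lung protocol spanning 280 s.
    """
    durations: list[float] = []
    for count, duration in spec:
        if int(count) != count or count <= 0:
            raise ValueError(f"frame count must be a positive integer, got {count}")
        if duration <= 0:
            raise ValueError(f"frame duration must be positive, got {duration}")
        durations.extend([float(duration)] * int(count))
    return FrameSchedule(tuple(durations), start_s=start_s)
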