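"""Time-activity curves and their extraction from dynamic images.

A :class:`TimeActivityCurve` is tracer concentration (kBq/mL) sampled at
stated times.  Region TACs are per-frame means over a VOI, anchored at
frame mid-times; the right-ventricle input TAC averages only the voxels
strictly above a per-frame percentile, to restrict the input to the
blood-filled cavity.  Kinetic analysis runs on a uniform 1 s grid spanning
0...280 s (281 samples), obtained by linear interpolation with the left
edge anchored at (0, 0) — no tracer is present at injection start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .frames import FrameSchedule
from .voi import BinaryMask, GeometryError

__all__ = [
    "TimeActivityCurve",
    "DynamicImage",
    "EmptyVoiError",
    "mean_tac",
    "percentile_input_tac",
    "interpolate_1s",
    "UNIFORM_GRID_END_S",
]

logger = logging.getLogger(__name__)

#: End of the uniform analysis grid (seconds); the grid is 0, 1, ..., 280.
UNIFORM_GRID_END_S = 280


class EmptyVoiError(ValueError):
    """A TAC was requested over a VOI containing no voxels."""


@dataclass(frozen=True)
class TimeActivityCurve:
    """Sampled tracer concentration over time.

    kind is "frame-mid" for per-frame region means timestamped at frame
    mid-times, "uniform-1s" for curves on the integer-second analysis grid.
    """

    times_s: np.ndarray
    values: np.ndarray
    kind: str = "frame-mid"
    name: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("times and values must be 1D and equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times_s)

    def with_values(self, values: np.ndarray) -> "TimeActivityCurve":
        return replace(self, values=values)


@dataclass(frozen=True)
class DynamicImage:
    """4D dynamic PET volume (x, y, z, frame) with timing and geometry."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: tuple[float, float, float] = (1.65, 1.65, 3.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"dynamic image must be 4D, got shape {arr.shape}")
        if arr.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame axis length {arr.shape[3]} != schedule frames "
                f"{self.schedule.n_frames}"
            )
        object.__setattr__(self, "data", arr)
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape


def _check_voi(image: DynamicImage, voi: BinaryMask) -> None:
    if voi.shape != image.shape[:3] or not np.allclose(
        voi.voxel_size_mm, image.voxel_size_mm
    ):
        raise GeometryError(
            f"VOI grid {voi.shape}/{voi.voxel_size_mm} does not match image "
            f"{image.shape[:3]}/{image.voxel_size_mm}"
        )
    if not voi.data.any():
        raise EmptyVoiError(f"VOI {voi.name!r} is empty")


def mean_tac(image: DynamicImage, voi: BinaryMask) -> TimeActivityCurve:
    """Per-frame mean over the VOI, timestamped at frame mid-times on the
    scan clock (so the uniform analysis grid covers the whole scan)."""
    _check_voi(image, voi)
    values = image.data[voi.data].mean(axis=0)
    return TimeActivityCurve(
        image.schedule.scan_mid_times_s, values, kind="frame-mid", name=voi.name
    )


def percentile_input_tac(
    image: DynamicImage, rv_voi: BinaryMask, p: float = 90.0
) -> TimeActivityCurve:
    """Mean TAC of the VOI voxels strictly above the p-th percentile,
    recomputed frame by frame.

    The subset of contributing voxels may differ between frames.  If every
    voxel in a frame has the same value (nothing strictly above the
    percentile), that frame falls back to the plain VOI mean and the
    fallback is logged.
    """
    _check_voi(image, rv_voi)
    voxels = image.data[rv_voi.data]  # (n_voxels, n_frames)
    values = np.empty(voxels.shape[1])
    for f in range(voxels.shape[1]):
        frame = voxels[:, f]
        threshold = np.percentile(frame, p)
        above = frame[frame > threshold]
        if above.size == 0:
            logger.warning(
                "frame %d: no voxels strictly above the %gth percentile; "
                "falling back to the plain VOI mean", f, p,
            )
            values[f] = frame.mean()
        else:
            values[f] = above.mean()
    return TimeActivityCurve(
        image.schedule.scan_mid_times_s, values, kind="frame-mid", name=rv_voi.name
    )


def interpolate_1s(
    tac: TimeActivityCurve, t_end: int = UNIFORM_GRID_END_S
) -> TimeActivityCurve:
    """Linearly interpolate a TAC onto the integer-second grid 0...t_end.

    Before the first sample the curve is interpolated from (0, 0) —
    concentrations are zero at injection start.  After the last sample the
    last value is held constant.  A curve already sampled exactly on the
    target grid is returned unchanged (bit-equal values).
    """
    if len(tac) < 2:
        raise ValueError("need at least 2 samples to interpolate")
    grid = np.arange(0.0, t_end + 1)
    if len(tac) == len(grid) and np.array_equal(tac.times_s, grid):
        return replace(tac, kind="uniform-1s")
    t, v = tac.times_s, tac.values
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[0.0], v])
    elif t[0] < 0:
        raise ValueError("TAC times must be non-negative")
    values = np.interp(grid, t, v)
    return TimeActivityCurve(grid, values, kind="uniform-1s", name=tac.name)
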