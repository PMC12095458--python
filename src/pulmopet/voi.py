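"""Volume-of-interest construction from binary segmentation masks.

Lung-lobe VOIs are turned into hollow shells (interior deeper than a few
voxels from the surface is removed, to cut down the air fraction), vessel
masks are dilated and subtracted (spill-over margin), and only the largest
connected component of each VOI is kept.  All morphology uses the
6-connected cross structuring element, iterated; connected components use
26-connectivity.  Morphology is voxel-metric: anisotropic voxel sizes are
deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "BinaryMask",
    "VoiRecipe",
    "GeometryError",
    "LOBE_NAMES",
    "RV_NAME",
    "VESSEL_NAMES",
    "resample_mask",
    "hollow_shell",
    "erode",
    "dilate",
    "subtract",
    "largest_connected_component",
    "build_vois",
]

#: Lung lobe labels: left/right lower, right middle, left/right upper.
LOBE_NAMES: tuple[str, ...] = ("LLL", "RLL", "RML", "LUL", "RUL")
RV_NAME = "RV"
#: Vessels removed (with a dilated margin) from the lung VOIs.
VESSEL_NAMES: tuple[str, ...] = (
    "subclavian_artery_left",
    "subclavian_artery_right",
    "brachiocephalic_vein_left",
    "brachiocephalic_vein_right",
)

# 6-connected cross (face adjacency) for erosion/dilation,
# 26-connectivity for component labelling.
_CROSS = ndimage.generate_binary_structure(3, 1)
_FULL = ndimage.generate_binary_structure(3, 3)


class GeometryError(ValueError):
    """Grids or physical extents of two masks are incompatible."""


@dataclass(frozen=True)
class BinaryMask:
    """A named boolean occupancy grid with voxel geometry.

    Parameters
    ----------
    data
        3D boolean array.
    voxel_size_mm
        Physical voxel edge lengths (x, y, z) in millimetres.
    name
        Label, e.g. a lobe name.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.65, 1.65, 3.0)
    name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=bool)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        object.__setattr__(self, "data", arr)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel size must be 3 positive floats, got {vs}")
        object.__setattr__(self, "voxel_size_mm", vs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def physical_extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size_mm))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray, name: str | None = None) -> "BinaryMask":
        return replace(self, data=data, name=self.name if name is None else name)

    def same_grid(self, other: "BinaryMask") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )


@dataclass(frozen=True)
class VoiRecipe:
    """Parameters of the VOI construction pipeline.

    shell_depth_voxels
        Lobe interior deeper than this many erosion steps from the surface
        is removed (hollow shell).  Default 3.
    vessel_dilation_iters
        Dilation iterations applied to vessel masks before subtraction;
        each iteration adds roughly one voxel of spill-over margin.
    vessel_names
        Masks subtracted from every lobe VOI.
    keep_largest_component
        Keep only the largest 26-connected component of each final VOI.
    """

    shell_depth_voxels: int = 3
    vessel_dilation_iters: int = 2
    vessel_names: tuple[str, ...] = VESSEL_NAMES
    keep_largest_component: bool = True

    def __post_init__(self) -> None:
        if self.shell_depth_voxels < 1:
            raise ValueError("shell depth must be >= 1 voxel")
        if self.vessel_dilation_iters < 0:
            raise ValueError("vessel dilation iterations must be >= 0")
        object.__setattr__(self, "vessel_names", tuple(self.vessel_names))


def resample_mask(mask: BinaryMask, target_shape: Sequence[int],
                  target_voxel_size_mm: Sequence[float]) -> BinaryMask:
    """Nearest-neighbour resampling onto a target grid sharing the same
    physical extent.

    Voxel centres of the target grid are mapped into source voxel indices;
    the source voxel containing each target centre supplies the value.
    """
    target_shape = tuple(int(s) for s in target_shape)
    target_vs = tuple(float(v) for v in target_voxel_size_mm)
    src_extent = mask.physical_extent_mm
    tgt_extent = tuple(s * v for s, v in zip(target_shape, target_vs))
    if not np.allclose(src_extent, tgt_extent, rtol=1e-6, atol=1e-6):
        raise GeometryError(
            f"physical extents differ: source {src_extent} mm vs target {tgt_extent} mm"
        )
    if target_shape == mask.shape:
        return BinaryMask(mask.data.copy(), target_vs, mask.name)
    out = mask.data
    for axis in range(3):
        centres = (np.arange(target_shape[axis]) + 0.5) * target_vs[axis]
        idx = np.floor(centres / mask.voxel_size_mm[axis]).astype(int)
        idx = np.clip(idx, 0, mask.shape[axis] - 1)
        out = np.take(out, idx, axis=axis)
    return BinaryMask(out, target_vs, mask.name)


def erode(mask: BinaryMask, iterations: int) -> BinaryMask:
    """Iterated binary erosion with the 6-connected cross element."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0 or not mask.data.any():
        return mask.with_data(mask.data.copy())
    out = ndimage.binary_erosion(mask.data, structure=_CROSS, iterations=iterations)
    return mask.with_data(out)


def hollow_shell(mask: BinaryMask, depth: int = 3) -> BinaryMask:
    """Remove the interior more than `depth` adjacent voxels from the surface.

    The result is ``mask \\ erode(mask, depth)``: every retained voxel lies
    within `depth` face-adjacency erosion steps of the mask boundary.  The
    shell and the eroded core partition the mask exactly.
    """
    if depth < 1:
        raise ValueError("shell depth must be >= 1")
    core = erode(mask, depth)
    return mask.with_data(mask.data & ~core.data)


def dilate(mask: BinaryMask, iterations: int) -> BinaryMask:
    """Iterated binary dilation with the 6-connected cross element.

    ``iterations=0`` is the identity.  Dilation is extensive: the input is
    always a subset of the output.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0 or not mask.data.any():
        return mask.with_data(mask.data.copy())
    out = ndimage.binary_dilation(mask.data, structure=_CROSS, iterations=iterations)
    return mask.with_data(out)


def subtract(mask: BinaryMask, others: Sequence[BinaryMask]) -> BinaryMask:
    """Set difference of `mask` and the union of `others` (same grid)."""
    out = mask.data.copy()
    for other in others:
        if not mask.same_grid(other):
            raise GeometryError(
                f"grid mismatch: {mask.shape}/{mask.voxel_size_mm} vs "
                f"{other.shape}/{other.voxel_size_mm}"
            )
        out &= ~other.data
    return mask.with_data(out)


def largest_connected_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 26-connected component.

    Ties are broken in favour of the component containing the smallest
    linear (C-order) voxel index.  An empty mask stays empty.
    """
    labels, n = ndimage.label(mask.data, structure=_FULL)
    if n == 0:
        return mask.with_data(mask.data.copy())
    counts = np.bincount(labels.ravel())[1:]  # skip background
    best = counts.max()
    candidates = np.flatnonzero(counts == best) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        keep = min(candidates, key=lambda lab: np.argmax(flat == lab))
    return mask.with_data(labels == keep)


def build_vois(
    masks: Mapping[str, BinaryMask],
    recipe: VoiRecipe = VoiRecipe(),
    target_shape: Sequence[int] | None = None,
    target_voxel_size_mm: Sequence[float] | None = None,
) -> dict[str, BinaryMask]:
    """Run the full VOI pipeline on a set of raw segmentation masks.

    Lobes: resample -> hollow shell -> subtract dilated vessels -> largest
    component.  Right ventricle: resample -> largest component.  Returns
    the five final lobe VOIs plus the RV VOI.
    """
    required = LOBE_NAMES + (RV_NAME,) + recipe.vessel_names
    missing = [name for name in required if name not in masks]
    if missing:
        raise KeyError(f"missing required masks: {missing}")

    def _resample(m: BinaryMask) -> BinaryMask:
        if target_shape is None:
            return m
        vs = target_voxel_size_mm
        if vs is None:
            raise ValueError("target voxel size required with target shape")
        return resample_mask(m, target_shape, vs)

    vessels = [
        dilate(_resample(masks[name]), recipe.vessel_dilation_iters)
        for name in recipe.vessel_names
    ]
    out: dict[str, BinaryMask] = {}
    for lobe in LOBE_NAMES:
        voi = hollow_shell(_resample(masks[lobe]), recipe.shell_depth_voxels)
        voi = subtract(voi, vessels)
        if recipe.keep_largest_component:
            voi = largest_connected_component(voi)
        out[lobe] = voi.with_data(voi.data, name=lobe)
    rv = _resample(masks[RV_NAME])
    if recipe.keep_largest_component:
        rv = largest_connected_component(rv)
    out[RV_NAME] = rv.with_data(rv.data, name=RV_NAME)
    return out
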