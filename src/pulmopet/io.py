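"""File formats: NIfTI volumes, JSON sidecars, TAC and cohort tables.

The dynamic image travels as a 4D NIfTI (.nii.gz) with a JSON sidecar
``{"frame_durations_s": [...], "start_s": ...}``; masks are 3D NIfTI;
TACs are two-column CSV (time_s, value_kBq_per_mL); cohorts and fit
results are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .frames import FrameSchedule
from .synthetic import PatientRecord
from .tac import DynamicImage, TimeActivityCurve
from .voi import BinaryMask

__all__ = [
    "save_dynamic_image",
    "load_dynamic_image",
    "save_mask",
    "load_mask",
    "save_masks",
    "load_masks",
    "save_tac",
    "load_tac",
    "save_cohort_table",
    "load_cohort_table",
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_dynamic_image(image: DynamicImage, path: str | Path) -> None:
    """Write the 4D volume plus its ``.json`` frame-timing sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), _affine(image.voxel_size_mm)), path)
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    sidecar = sidecar.with_suffix(".json")
    sidecar.write_text(json.dumps(image.schedule.to_dict(), indent=2))


def load_dynamic_image(path: str | Path) -> DynamicImage:
    path = Path(path)
    img = nib.load(path)
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    sidecar = sidecar.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"frame-timing sidecar not found: {sidecar}")
    schedule = FrameSchedule.from_dict(json.loads(sidecar.read_text()))
    voxel = tuple(float(abs(v)) for v in np.diag(img.affine)[:3])
    return DynamicImage(np.asarray(img.dataobj, dtype=float), schedule, voxel)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.voxel_size_mm)), Path(path)
    )


def load_mask(path: str | Path, name: str = "") -> BinaryMask:
    img = nib.load(Path(path))
    voxel = tuple(float(abs(v)) for v in np.diag(img.affine)[:3])
    return BinaryMask(np.asarray(img.dataobj) > 0, voxel, name or Path(path).stem)


def save_masks(masks: Mapping[str, BinaryMask], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in masks.items():
        save_mask(mask, directory / f"{name}.nii.gz")


def load_masks(directory: str | Path) -> dict[str, BinaryMask]:
    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob("*.nii.gz")):
        name = path.name[: -len(".nii.gz")]
        out[name] = load_mask(path, name)
    if not out:
        raise FileNotFoundError(f"no .nii.gz masks found in {directory}")
    return out


def save_tac(tac: TimeActivityCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": tac.times_s, "value_kBq_per_mL": tac.values}
    ).to_csv(Path(path), index=False)


def load_tac(path: str | Path, kind: str = "uniform-1s", name: str = "") -> TimeActivityCurve:
    df = pd.read_csv(Path(path))
    return TimeActivityCurve(
        df["time_s"].to_numpy(float),
        df["value_kBq_per_mL"].to_numpy(float),
        kind=kind,
        name=name or Path(path).stem,
    )


def save_cohort_table(records: list[PatientRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "sex": r.sex,
            "age": r.age,
            "weight": r.weight,
            "bmi": r.bmi,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
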