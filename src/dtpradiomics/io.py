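"""Reading and writing SUV volumes, lesion masks, and feature tables.

Conventions used throughout the package: voxel indexing is 0-based,
bounding boxes are half-open ``[start, stop)``, and world coordinates are
millimetres taken from the NIfTI affine.  SUV values are assumed to be
pre-computed (g/mL); no dose/body-weight conversion is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SUVVolume",
    "LesionMask",
    "read_suv_volume",
    "write_suv_volume",
    "read_mask",
    "write_mask",
    "write_feature_table",
    "read_feature_table",
    "write_seed_regions",
    "read_seed_regions",
    "FEATURE_TABLE_COLUMNS",
]

#: Stable long-format schema for feature tables (the interchange contract
#: between the extraction and classification stages).
FEATURE_TABLE_COLUMNS = [
    "patient",
    "lesion",
    "day",
    "time_min",
    "reconstruction",
    "delineation",
    "discretization",
    "feature",
    "value",
]


@dataclass
class SUVVolume:
    """A 3-D standardized-uptake-value image.

    Parameters
    ----------
    values
        3-D array of SUV in g/mL; must be finite and non-negative.
    voxel_size_mm
        Per-axis voxel spacing in mm (positive).
    origin_mm
        World coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"SUV volume must be 3-D, got {self.values.ndim}-D data"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV volume contains non-finite voxels")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel spacing must be 3 positive reals, got {self.voxel_size_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass
class LesionMask:
    """Binary voxel mask congruent with its parent volume."""

    mask: np.ndarray
    lesion_id: str = "lesion"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got {self.mask.ndim}-D data")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def read_suv_volume(path: str | Path) -> SUVVolume:
    """Load a NIfTI-1 file as an SUV volume.

    Spacing is taken from the header; the data must be 3-D scalar and
    finite.  Values are interpreted as SUV in g/mL.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected 3-D scalar data, got {data.ndim}-D"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return SUVVolume(values=data.astype(np.float64), voxel_size_mm=spacing, origin_mm=origin)


def write_suv_volume(volume: SUVVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (float32)."""
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.affine())
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))


def write_mask(mask: LesionMask, volume: SUVVolume, path: str | Path) -> None:
    """Write a lesion mask as NIfTI-1 with the parent volume's geometry."""
    if mask.mask.shape != volume.shape:
        raise ValueError("mask shape does not match parent volume")
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), volume.affine())
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))


def read_mask(path: str | Path, lesion_id: str = "lesion") -> LesionMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D mask, got {data.ndim}-D")
    return LesionMask(mask=data > 0, lesion_id=lesion_id)


def write_feature_table(table: pd.DataFrame, path: str | Path, overwrite: bool = False) -> None:
    """Persist a long-format feature table as UTF-8 CSV.

    The schema is :data:`FEATURE_TABLE_COLUMNS` in that order; values are
    written with 12 significant digits so that a read round-trip restores
    them to that precision.
    """
    path = Path(path)
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns {missing}")
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    table[FEATURE_TABLE_COLUMNS].to_csv(
        path, index=False, float_format="%.12g", encoding="utf-8"
    )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_seed_regions(seed_boxes: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-lesion seed bounding boxes as a JSON sidecar.

    ``seed_boxes`` maps lesion id to a (3, 2) integer array of half-open
    0-based voxel index ranges.
    """
    payload = {
        "index_convention": "0-based, half-open [start, stop)",
        "lesions": {
            lid: [[int(a), int(b)] for a, b in np.asarray(box)]
            for lid, box in seed_boxes.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_seed_regions(path: str | Path) -> dict[str, np.ndarray]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return {
        lid: np.asarray(box, dtype=int) for lid, box in payload["lesions"].items()
    }
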