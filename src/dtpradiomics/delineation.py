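"""Lesion delineation on SUV volumes.

Implements the three segmentation strategies commonly applied to FDG-PET
lesions — a relative isocontour at 40% of the lesion's SUVmax (PCT40), a
fixed isocontour at SUV 4.0 g/mL (SUV4), and a contrast-based isocontour at
``0.5 * SUVpeak + background`` — together with the SUVpeak estimator (mean
over a 1 mL sphere), the background-shell estimator, and a minimum-size
qualification filter (64 voxels).

All thresholds are applied as closed inequalities (``SUV >= threshold``;
configurable) and masks are restricted to the 26-connected component that
contains the seed region's hottest voxel, so adjacent lesions above the
same threshold are not merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .io import LesionMask, SUVVolume

__all__ = [
    "SeedRegion",
    "DelineationMethod",
    "DelineationResult",
    "suv_peak",
    "delineate_threshold",
    "delineate_contrast",
    "delineate",
    "background_shell_mean",
    "MIN_QUALIFYING_VOXELS",
]

#: Lesions smaller than this (in voxels) do not qualify for feature extraction.
MIN_QUALIFYING_VOXELS = 64

#: 3x3x3 structuring element: 26-connectivity.
_CONN26 = np.ones((3, 3, 3), dtype=bool)


class DelineationMethod(str, Enum):
    PCT40 = "PCT40"
    SUV4 = "SUV4"
    CONTRAST = "CONTRAST"


@dataclass
class SeedRegion:
    """Half-open 0-based voxel-index bounding box localizing one lesion."""

    bbox: np.ndarray  # (3, 2) int

    def __post_init__(self) -> None:
        self.bbox = np.asarray(self.bbox, dtype=int)
        if self.bbox.shape != (3, 2):
            raise ValueError("seed bbox must be a (3, 2) index array")
        if np.any(self.bbox[:, 1] <= self.bbox[:, 0]):
            raise ValueError("seed bbox must contain at least one voxel")

    def slices(self, shape: tuple[int, int, int] | None = None) -> tuple[slice, ...]:
        box = self.bbox
        if shape is not None:
            box = np.stack(
                [np.clip(box[:, 0], 0, shape), np.clip(box[:, 1], 0, shape)], axis=1
            )
            if np.any(box[:, 1] <= box[:, 0]):
                raise ValueError("seed bbox does not intersect the volume")
        return tuple(slice(a, b) for a, b in box)


@dataclass
class DelineationResult:
    """One delineated lesion plus the quantities used to obtain it."""

    mask: LesionMask
    method: DelineationMethod
    threshold_used: float
    suv_max: float
    suv_peak: float
    background_suv: float | None
    qualifies: bool

    @property
    def n_voxels(self) -> int:
        return self.mask.n_voxels


def _seed_argmax(volume: SUVVolume, seed: SeedRegion) -> tuple[int, int, int]:
    """Index of the hottest voxel inside the seed region."""
    sl = seed.slices(volume.shape)
    sub = volume.values[sl]
    if sub.size == 0:
        raise ValueError("seed region is empty")
    local = np.unravel_index(np.argmax(sub), sub.shape)
    return tuple(int(local[a] + sl[a].start) for a in range(3))


def _sphere_offsets(voxel_size_mm, radius_mm: float) -> np.ndarray:
    """Voxel offsets whose centers lie within radius_mm of the center voxel."""
    half = [int(np.floor(radius_mm / s)) for s in voxel_size_mm]
    grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    d2 = np.sum((offs * np.asarray(voxel_size_mm)) ** 2, axis=1)
    return offs[d2 <= radius_mm**2 + 1e-9]


def suv_peak(
    volume: SUVVolume, seed: SeedRegion, sphere_volume_ml: float = 1.0
) -> float:
    """SUVpeak: the highest mean SUV of a ~1 mL sphere centered in the seed.

    The sphere is the set of voxels whose centers lie within the sphere
    radius of the candidate center voxel; the center is chosen to maximize
    the sphere mean over the seed region (EANM-style).  Spheres that extend
    beyond the volume are clipped with a warning and averaged over the
    in-bounds voxels only.
    """
    radius_mm = (3.0 * sphere_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    offsets = _sphere_offsets(volume.voxel_size_mm, radius_mm)
    sl = seed.slices(volume.shape)
    vals = volume.values
    shape = np.asarray(vals.shape)

    centers = np.stack(
        np.meshgrid(*[np.arange(s.start, s.stop) for s in sl], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    sums = np.zeros(len(centers))
    counts = np.zeros(len(centers), dtype=int)
    for off in offsets:
        pos = centers + off
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        sums[ok] += vals[pos[ok, 0], pos[ok, 1], pos[ok, 2]]
        counts[ok] += 1
    means = sums / counts
    best = int(np.argmax(means))
    if counts[best] < len(offsets):
        warnings.warn(
            "SUVpeak sphere clipped at the volume boundary; mean taken over "
            "in-bounds voxels",
            stacklevel=2,
        )
    return float(means[best])


def _component_mask(
    volume: SUVVolume,
    seed: SeedRegion,
    threshold: float,
    closed: bool = True,
) -> np.ndarray:
    """Supra-threshold 26-connected component containing the seed's hottest voxel."""
    vals = volume.values
    candidate = vals >= threshold if closed else vals > threshold
    if not candidate.any():
        return np.zeros(vals.shape, dtype=bool)
    peak_idx = _seed_argmax(volume, seed)
    if not candidate[peak_idx]:
        return np.zeros(vals.shape, dtype=bool)
    labels, _ = ndimage.label(candidate, structure=_CONN26)
    return labels == labels[peak_idx]


def delineate_threshold(
    volume: SUVVolume,
    seed: SeedRegion,
    mode: DelineationMethod | str,
    closed: bool = True,
    min_voxels: int = MIN_QUALIFYING_VOXELS,
) -> DelineationResult:
    """Isocontour delineation at 40% of seed SUVmax (PCT40) or SUV 4.0 (SUV4).

    The returned mask is the 26-connected supra-threshold component that
    contains the hottest voxel of the seed region.  An empty mask (e.g.
    SUV4 on a lesion with SUVmax < 4) yields a degenerate result with
    ``qualifies=False``.
    """
    mode = DelineationMethod(mode)
    smax = float(volume.values[seed.slices(volume.shape)].max())
    if mode is DelineationMethod.PCT40:
        threshold = 0.40 * smax
    elif mode is DelineationMethod.SUV4:
        threshold = 4.0
    else:
        raise ValueError("use delineate_contrast() for the contrast-based method")
    mask = _component_mask(volume, seed, threshold, closed=closed)
    n = int(mask.sum())
    return DelineationResult(
        mask=LesionMask(mask),
        method=mode,
        threshold_used=float(threshold),
        suv_max=smax,
        suv_peak=suv_peak(volume, seed),
        background_suv=None,
        qualifies=n >= min_voxels,
    )


def background_shell_mean(
    volume: SUVVolume,
    seed: SeedRegion,
    shell_distance_mm: float = 20.0,
    exclude_above_suv: float = 4.0,
    closed: bool = True,
) -> float:
    """Mean SUV in a one-voxel-thick shell 2 cm from the 70%-of-SUVmax volume.

    Distances are Euclidean distances (mm) to the nearest voxel of the 70%
    volume, computed by a Euclidean distance transform of its complement;
    the shell spans ``[shell_distance_mm, shell_distance_mm + pitch)`` with
    pitch the smallest voxel edge.  Voxels with SUV above
    ``exclude_above_suv`` are excluded (they likely belong to other hot
    structures).
    """
    smax = float(volume.values[seed.slices(volume.shape)].max())
    core = _component_mask(volume, seed, 0.70 * smax, closed=closed)
    if not core.any():
        raise ValueError("70%-of-SUVmax volume is empty; cannot place background shell")
    dist = ndimage.distance_transform_edt(~core, sampling=volume.voxel_size_mm)
    pitch = min(volume.voxel_size_mm)
    shell = (dist >= shell_distance_mm) & (dist < shell_distance_mm + pitch)
    shell &= volume.values <= exclude_above_suv
    if not shell.any():
        raise ValueError("no valid background: shell empty after SUV exclusion")
    return float(volume.values[shell].mean())


def delineate_contrast(
    volume: SUVVolume,
    seed: SeedRegion,
    closed: bool = True,
    min_voxels: int = MIN_QUALIFYING_VOXELS,
) -> DelineationResult:
    """Contrast-based isocontour at ``0.5 * SUVpeak + background SUV``."""
    peak = suv_peak(volume, seed)
    background = background_shell_mean(volume, seed, closed=closed)
    threshold = 0.5 * peak + background
    mask = _component_mask(volume, seed, threshold, closed=closed)
    n = int(mask.sum())
    smax = float(volume.values[seed.slices(volume.shape)].max())
    return DelineationResult(
        mask=LesionMask(mask),
        method=DelineationMethod.CONTRAST,
        threshold_used=float(threshold),
        suv_max=smax,
        suv_peak=peak,
        background_suv=background,
        qualifies=n >= min_voxels,
    )


def delineate(
    volume: SUVVolume,
    seed: SeedRegion,
    method: DelineationMethod | str,
    **kwargs,
) -> DelineationResult:
    """Dispatch to the requested delineation method."""
    method = DelineationMethod(method)
    if method is DelineationMethod.CONTRAST:
        return delineate_contrast(volume, seed, **kwargs)
    return delineate_threshold(volume, seed, method, **kwargs)
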