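"""Intensity discretization of a lesion's SUVs into integer gray levels.

Two schemes are supported:

* **FBW** (fixed bin width): ``level = floor((SUV - range_min) / W) + 1``
  with a fixed SUV range (defaults 0-60 g/mL at W = 0.25 g/mL, i.e. 240
  levels).  Comparable across lesions because the bin edges are absolute.
* **FBN** (fixed bin number): N bins stretched over the lesion's own
  SUVmin-SUVmax range, ``level = min(N, floor(N*(SUV - min)/(max - min)) + 1)``.
  Invariant to affine rescaling of the lesion's intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["BinningConfig", "DiscretizedROI", "discretize"]


@dataclass(frozen=True)
class BinningConfig:
    """Discretization settings.

    ``scheme`` is ``"FBW"`` or ``"FBN"``; FBW uses ``bin_width`` over
    ``[range_min, range_max]`` (g/mL), FBN uses ``n_bins`` over the
    lesion's own range.
    """

    scheme: str = "FBW"
    bin_width: float = 0.25
    range_min: float = 0.0
    range_max: float = 60.0
    n_bins: int = 64

    def __post_init__(self) -> None:
        if self.scheme not in ("FBW", "FBN"):
            raise ValueError(f"unknown binning scheme {self.scheme!r}")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.range_max <= self.range_min:
            raise ValueError("range_max must exceed range_min")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")

    @property
    def n_levels_fbw(self) -> int:
        return int(np.ceil((self.range_max - self.range_min) / self.bin_width))


@dataclass
class DiscretizedROI:
    """Gray-level image of one lesion.

    ``levels`` is a 3-D integer array over the lesion's bounding box with
    values in ``1..n_levels`` inside the mask and 0 outside.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("gray levels outside [1, n_levels]")

    @property
    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(
    values: np.ndarray,
    mask: np.ndarray,
    config: BinningConfig,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> DiscretizedROI:
    """Discretize the masked SUVs of a volume into gray levels.

    The output is cropped to the mask's bounding box.  Under FBW, SUVs
    outside the configured range are clamped to the first/last level with
    a warning.  Under FBN, a degenerate lesion (SUVmax == SUVmin) maps to
    a single level.
    """
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask shapes differ")
    if not mask.any():
        raise ValueError("cannot discretize an empty ROI")

    # crop to bounding box
    idx = np.nonzero(mask)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    vals = values[sl]
    msk = mask[sl]
    roi = vals[msk]

    if config.scheme == "FBW":
        n_levels = config.n_levels_fbw
        if roi.min() < config.range_min or roi.max() > config.range_max:
            warnings.warn(
                "SUVs outside the fixed binning range; clamping to boundary levels",
                stacklevel=2,
            )
        lv = np.floor((vals - config.range_min) / config.bin_width).astype(np.int64) + 1
        lv = np.clip(lv, 1, n_levels)
    else:  # FBN
        vmin = roi.min()
        vmax = roi.max()
        if vmax == vmin:
            lv = np.ones_like(vals, dtype=np.int64)
            n_levels = 1
        else:
            n_levels = config.n_bins
            lv = np.floor(n_levels * (vals - vmin) / (vmax - vmin)).astype(np.int64) + 1
            lv = np.minimum(lv, n_levels)
            lv = np.maximum(lv, 1)

    lv[~msk] = 0
    return DiscretizedROI(
        levels=lv, mask=msk, n_levels=n_levels, voxel_size_mm=tuple(voxel_size_mm)
    )
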