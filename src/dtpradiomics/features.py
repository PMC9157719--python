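"""The 49-feature PET radiomics panel.

Seven classes with fixed cardinalities 6/5/6/7/11/11/3:

* conventional (6): SUVmin, SUVmean, SUVstd, SUVmax, SUVpeak, TLG
* shape (5): volume (mL and voxels), surface area, sphericity, compacity
* histogram (6): skewness, kurtosis, excess kurtosis, entropy (log10 and
  log2), energy — computed on the discretized gray-level histogram
* GLCM (7), GLRLM (11), GLZLM (11), NGLDM (3): see
  :mod:`dtpradiomics.texture`.

Conventional and shape features depend only on the SUVs and the mask, not
on the discretization; features are extracted only for lesions with at
least 64 voxels.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage import measure

from .delineation import DelineationResult
from .discretize import BinningConfig, DiscretizedROI, discretize
from .io import SUVVolume
from .texture import glcm_features, glrlm_features, glzlm_features, ngldm_features

__all__ = [
    "FEATURE_CLASSES",
    "FEATURE_NAMES",
    "conventional_and_shape",
    "histogram_features",
    "extract_all",
]

log = logging.getLogger(__name__)

FEATURE_CLASSES: dict[str, list[str]] = {
    "conventional": [
        "CONV_SUVmin",
        "CONV_SUVmean",
        "CONV_SUVstd",
        "CONV_SUVmax",
        "CONV_SUVpeak",
        "CONV_TLG",
    ],
    "shape": [
        "SHAPE_volume_mL",
        "SHAPE_volume_vx",
        "SHAPE_surface_mm2",
        "SHAPE_sphericity",
        "SHAPE_compacity",
    ],
    "histogram": [
        "HIST_skewness",
        "HIST_kurtosis",
        "HIST_excess_kurtosis",
        "HIST_entropy_log10",
        "HIST_entropy_log2",
        "HIST_energy",
    ],
    "glcm": [
        "GLCM_homogeneity",
        "GLCM_energy",
        "GLCM_contrast",
        "GLCM_correlation",
        "GLCM_entropy_log10",
        "GLCM_entropy_log2",
        "GLCM_dissimilarity",
    ],
    "glrlm": [
        "GLRLM_SRE",
        "GLRLM_LRE",
        "GLRLM_LGRE",
        "GLRLM_HGRE",
        "GLRLM_SRLGE",
        "GLRLM_SRHGE",
        "GLRLM_LRLGE",
        "GLRLM_LRHGE",
        "GLRLM_GLNU",
        "GLRLM_RLNU",
        "GLRLM_RP",
    ],
    "glzlm": [
        "GLZLM_SZE",
        "GLZLM_LZE",
        "GLZLM_LGZE",
        "GLZLM_HGZE",
        "GLZLM_SZLGE",
        "GLZLM_SZHGE",
        "GLZLM_LZLGE",
        "GLZLM_LZHGE",
        "GLZLM_GLNU",
        "GLZLM_ZLNU",
        "GLZLM_ZP",
    ],
    "ngldm": ["NGLDM_coarseness", "NGLDM_contrast", "NGLDM_busyness"],
}

#: All 49 feature identifiers in stable order.
FEATURE_NAMES: list[str] = [n for names in FEATURE_CLASSES.values() for n in names]


def conventional_and_shape(
    volume: SUVVolume, delineation: DelineationResult
) -> dict[str, float]:
    """Six conventional SUV metrics and five shape features.

    TLG is SUVmean x metabolic volume (mL).  The surface area comes from a
    marching-cubes mesh of the mask (voxel-face counting overestimates the
    area of smooth objects and would bias sphericity).  Sphericity is
    ``pi^(1/3) (6V)^(2/3) / A`` and compacity ``A^(3/2) / V`` with V in
    mm^3 and A in mm^2.
    """
    mask = delineation.mask.mask
    roi = volume.values[mask]
    if roi.size == 0:
        raise ValueError("empty mask")
    n_vx = int(mask.sum())
    vol_mm3 = n_vx * volume.voxel_volume_mm3
    vol_ml = vol_mm3 / 1000.0
    mean = float(roi.mean())

    # slight mask anti-aliasing before meshing: a raw binary marching-cubes
    # surface is faceted and overestimates the area of smooth objects
    padded = ndimage.gaussian_filter(np.pad(mask.astype(float), 2), 0.5)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=volume.voxel_size_mm
    )
    area = float(measure.mesh_surface_area(verts, faces))
    sphericity = float(np.pi ** (1 / 3) * (6.0 * vol_mm3) ** (2 / 3) / area)
    compacity = float(area**1.5 / vol_mm3)

    return {
        "CONV_SUVmin": float(roi.min()),
        "CONV_SUVmean": mean,
        "CONV_SUVstd": float(roi.std()),
        "CONV_SUVmax": float(roi.max()),
        "CONV_SUVpeak": float(delineation.suv_peak),
        "CONV_TLG": mean * vol_ml,
        "SHAPE_volume_mL": vol_ml,
        "SHAPE_volume_vx": float(n_vx),
        "SHAPE_surface_mm2": area,
        "SHAPE_sphericity": sphericity,
        "SHAPE_compacity": compacity,
    }


def histogram_features(d: DiscretizedROI) -> dict[str, float]:
    """Six features of the discretized gray-level histogram.

    Moments use the population convention; a zero-variance (single-level)
    histogram gets skewness = kurtosis = excess kurtosis = 0.
    """
    lv = d.masked_levels.astype(float)
    p = np.bincount(d.masked_levels - 1, minlength=d.n_levels) / lv.size
    nz = p[p > 0]
    mu = lv.mean()
    m2 = float(((lv - mu) ** 2).mean())
    if m2 > 0:
        m3 = float(((lv - mu) ** 3).mean())
        m4 = float(((lv - mu) ** 4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
        exkurt = kurt - 3.0
    else:
        skew = kurt = exkurt = 0.0
    return {
        "HIST_skewness": skew,
        "HIST_kurtosis": kurt,
        "HIST_excess_kurtosis": exkurt,
        "HIST_entropy_log10": float(-np.sum(nz * np.log10(nz))),
        "HIST_entropy_log2": float(-np.sum(nz * np.log2(nz))),
        "HIST_energy": float(np.sum(nz**2)),
    }


def extract_all(
    volume: SUVVolume,
    delineation: DelineationResult,
    config: BinningConfig,
) -> dict[str, float] | None:
    """Extract the full 49-feature panel for one delineated lesion.

    Returns ``None`` (and logs the exclusion) for lesions that do not
    qualify (< 64 voxels).  The returned dict has exactly the 49 keys of
    :data:`FEATURE_NAMES`, in that order.
    """
    if not delineation.qualifies:
        log.warning(
            "lesion %s excluded: %d voxels (< 64)",
            delineation.mask.lesion_id,
            delineation.n_voxels,
        )
        return None
    d = discretize(
        volume.values, delineation.mask.mask, config, voxel_size_mm=volume.voxel_size_mm
    )
    feats: dict[str, float] = {}
    feats.update(conventional_and_shape(volume, delineation))
    feats.update(histogram_features(d))
    feats.update({f"GLCM_{k}": v for k, v in glcm_features(d).items()})
    feats.update({f"GLRLM_{k}": v for k, v in glrlm_features(d).items()})
    feats.update({f"GLZLM_{k}": v for k, v in glzlm_features(d).items()})
    feats.update({f"NGLDM_{k}": v for k, v in ngldm_features(d).items()})
    return {name: feats[name] for name in FEATURE_NAMES}
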