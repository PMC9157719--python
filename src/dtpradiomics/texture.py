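"""3-D gray-level texture matrices and their features.

Four matrix families are computed from a discretized lesion
(:class:`~dtpradiomics.discretize.DiscretizedROI`):

* GLCM   — co-occurrence of level pairs at Chebyshev distance 1,
* GLRLM  — runs of equal level along discrete directions,
* GLZLM  — 26-connected equal-level zones (size-zone matrix),
* NGLDM  — neighborhood gray-level difference accumulators
           (coarseness / contrast / busyness).

GLCM and GLRLM pool all 13 unique 3-D unit directions (both orientations)
into a single matrix before computing features, following the convention
of LIFEx-style PET radiomics tools; the direction list is configurable.
Feature formulas follow the standardized (IBSI) definitions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glzlm_matrix",
    "glzlm_features",
    "ngldm_table",
    "ngldm_features",
    "COARSENESS_CAP",
]

#: The 13 unique unit directions of the 26-neighborhood (one orientation each).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: Value reported for NGLDM coarseness when its denominator vanishes
#: (perfectly homogeneous ROI).
COARSENESS_CAP = 1e6

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _offset_slices(shape, d):
    """Slice pair (at p, at p+d) covering all in-bounds positions."""
    sl_a, sl_b = [], []
    for di, s in zip(d, shape):
        sl_a.append(slice(max(0, -di), s - max(0, di)))
        sl_b.append(slice(max(0, di), s - max(0, -di)))
    return tuple(sl_a), tuple(sl_b)


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(d: DiscretizedROI, directions=DIRECTIONS_13) -> np.ndarray:
    """Pooled symmetric co-occurrence matrix, normalized to probabilities."""
    lv, mask, G = d.levels, d.mask, d.n_levels
    counts = np.zeros((G, G), dtype=np.int64)
    for off in directions:
        sa, sb = _offset_slices(lv.shape, off)
        valid = mask[sa] & mask[sb]
        a = lv[sa][valid] - 1
        b = lv[sb][valid] - 1
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("GLCM undefined: no neighboring voxel pairs in the ROI")
    return counts / total


def glcm_features(d: DiscretizedROI, directions=DIRECTIONS_13) -> dict[str, float]:
    """Seven co-occurrence features from the pooled matrix."""
    if d.n_voxels < 2:
        raise ValueError("GLCM features require at least 2 voxels")
    P = glcm_matrix(d, directions)
    G = P.shape[0]
    i = np.arange(1, G + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float(np.sum(i * px))
    var = float(np.sum((i - mu) ** 2 * px))
    nz = P[P > 0]
    if var > 0:
        correlation = float((np.sum(I * J * P) - mu * mu) / var)
    else:
        correlation = 1.0  # single-level ROI: perfectly correlated by convention
    ent2 = float(-np.sum(nz * np.log2(nz)))
    return {
        "homogeneity": float(np.sum(P / (1.0 + np.abs(I - J)))),
        "energy": float(np.sum(P * P)),
        "contrast": float(np.sum((I - J) ** 2 * P)),
        "correlation": correlation,
        "entropy_log10": float(-np.sum(nz * np.log10(nz))),
        "entropy_log2": ent2,
        "dissimilarity": float(np.sum(np.abs(I - J) * P)),
    }


# ---------------------------------------------------------------------------
# GLRLM


def _runs_for_direction(lv, mask, off):
    """(level, length) of every maximal equal-level run along one direction."""
    shape = np.asarray(lv.shape)
    d = np.asarray(off)
    # a voxel starts a run if its predecessor along -d is not in-mask same-level
    pred_same = np.zeros(mask.shape, dtype=bool)
    sa, sb = _offset_slices(lv.shape, tuple(-d))
    pred_same[sa] = mask[sa] & mask[sb] & (lv[sa] == lv[sb])
    starts = np.argwhere(mask & ~pred_same)
    levels = lv[tuple(starts.T)]
    lengths = np.ones(len(starts), dtype=np.int64)
    pos = starts.copy()
    active = np.arange(len(starts))
    while active.size:
        nxt = pos[active] + d
        inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
        cont = np.zeros(active.size, dtype=bool)
        if inb.any():
            c = nxt[inb]
            cont[inb] = mask[c[:, 0], c[:, 1], c[:, 2]] & (
                lv[c[:, 0], c[:, 1], c[:, 2]] == levels[active[inb]]
            )
        active = active[cont]
        lengths[active] += 1
        pos[active] += d
    return levels, lengths


def glrlm_matrix(d: DiscretizedROI, directions=DIRECTIONS_13) -> np.ndarray:
    """Run-length counts pooled over directions; rows levels, columns lengths."""
    all_lv, all_len = [], []
    for off in directions:
        lvs, lens = _runs_for_direction(d.levels, d.mask, off)
        all_lv.append(lvs)
        all_len.append(lens)
    lvs = np.concatenate(all_lv)
    lens = np.concatenate(all_len)
    R = np.zeros((d.n_levels, int(lens.max())), dtype=np.int64)
    np.add.at(R, (lvs - 1, lens - 1), 1)
    return R


def _run_zone_features(M: np.ndarray, prefix_short: str) -> dict[str, float]:
    """The shared 10 emphasis/nonuniformity features of GLRLM and GLZLM.

    ``M[i-1, l-1]`` counts runs (or zones) of level i and length (size) l.
    """
    G, L = M.shape
    i2 = np.arange(1, G + 1, dtype=float) ** 2
    l2 = np.arange(1, L + 1, dtype=float) ** 2
    N = M.sum()
    by_level = M.sum(axis=1).astype(float)
    by_len = M.sum(axis=0).astype(float)
    s = prefix_short  # 'R' for runs, 'Z' for zones
    return {
        f"S{s}E": float(np.sum(M / l2[None, :]) / N),
        f"L{s}E": float(np.sum(M * l2[None, :]) / N),
        f"LG{s}E": float(np.sum(M / i2[:, None]) / N),
        f"HG{s}E": float(np.sum(M * i2[:, None]) / N),
        f"S{s}LGE": float(np.sum(M / (i2[:, None] * l2[None, :])) / N),
        f"S{s}HGE": float(np.sum(M * i2[:, None] / l2[None, :]) / N),
        f"L{s}LGE": float(np.sum(M * l2[None, :] / i2[:, None]) / N),
        f"L{s}HGE": float(np.sum(M * i2[:, None] * l2[None, :]) / N),
        "GLNU": float(np.sum(by_level**2) / N),
        f"{s}LNU": float(np.sum(by_len**2) / N),
    }


def glrlm_features(d: DiscretizedROI, directions=DIRECTIONS_13) -> dict[str, float]:
    """Eleven run-length features; RP is normalized by voxels x directions."""
    R = glrlm_matrix(d, directions)
    feats = _run_zone_features(R, "R")
    feats["RP"] = float(R.sum() / (len(directions) * d.n_voxels))
    return feats


# ---------------------------------------------------------------------------
# GLZLM


def glzlm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Zone counts by (level, zone size); zones are 26-connected."""
    lv = d.levels
    sizes_by_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for g in np.unique(lv[d.mask]):
        labels, n = ndimage.label(lv == g, structure=_CONN26)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        sizes_by_level.append((int(g), sizes))
        max_size = max(max_size, int(sizes.max()))
    Z = np.zeros((d.n_levels, max_size), dtype=np.int64)
    for g, sizes in sizes_by_level:
        np.add.at(Z, (g - 1, sizes - 1), 1)
    return Z


def glzlm_features(d: DiscretizedROI) -> dict[str, float]:
    """Eleven size-zone features; ZP = zones / voxels."""
    Z = glzlm_matrix(d)
    feats = _run_zone_features(Z, "Z")
    feats["ZP"] = float(Z.sum() / d.n_voxels)
    return feats


# ---------------------------------------------------------------------------
# NGLDM (neighborhood gray-level difference)


def ngldm_table(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Per-level accumulators (n_i, s_i) of the neighborhood differences.

    ``n_i`` counts masked voxels of level i that have at least one in-mask
    26-neighbor; ``s_i`` accumulates |i - mean neighbor level| over those
    voxels.  Raises if no voxel has an in-mask neighbor.
    """
    lv, mask, G = d.levels, d.mask, d.n_levels
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.correlate(lv.astype(float) * mask, kernel, mode="constant")
    nbr_cnt = ndimage.correlate(mask.astype(float), kernel, mode="constant")
    valid = mask & (nbr_cnt > 0.5)
    if not valid.any():
        raise ValueError("NGLDM undefined: no masked voxel has an in-mask neighbor")
    A = nbr_sum[valid] / nbr_cnt[valid]
    levels = lv[valid]
    n_i = np.bincount(levels - 1, minlength=G).astype(float)
    s_i = np.bincount(levels - 1, weights=np.abs(levels - A), minlength=G)
    return n_i, s_i


def ngldm_features(
    d: DiscretizedROI, coarseness_cap: float = COARSENESS_CAP
) -> dict[str, float]:
    """Coarseness, contrast and busyness from neighborhood level differences.

    Voxels without in-mask neighbors are skipped; if no voxel has a
    neighbor the features are undefined.  A perfectly homogeneous ROI has
    zero accumulated difference, in which case coarseness is capped at
    ``coarseness_cap`` and contrast and busyness are 0.
    """
    G = d.n_levels
    n_i, s_i = ngldm_table(d)
    Nv = int(n_i.sum())
    p_i = n_i / Nv
    present = p_i > 0
    Ngp = int(present.sum())
    ps = float(np.sum(p_i * s_i))

    coarseness = 1.0 / ps if ps > 0 else coarseness_cap
    coarseness = min(coarseness, coarseness_cap)

    if Ngp > 1:
        i = np.arange(1, G + 1, dtype=float)
        pi = p_i[present]
        ii = i[present]
        diff2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = float(
            np.sum(pi[:, None] * pi[None, :] * diff2) / (Ngp * (Ngp - 1))
            * (s_i.sum() / Nv)
        )
        denom = np.sum(np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]))
        busyness = float(ps / denom) if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0

    return {"coarseness": float(coarseness), "contrast": contrast, "busyness": busyness}
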