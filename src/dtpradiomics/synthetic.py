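"""Synthetic dual-time-point FDG-PET test-retest studies.

Emulates the statistical structure of a double-baseline dual-uptake-time
design: each patient carries 1-10 ellipsoidal lesions with relatively high
uptake on a low uniform background, scanned on 2 days at ~60 and ~90 min
post-injection.  Each lesion has

* a smooth radial falloff profile (plateau, cosine roll-off to zero),
* a multiplicative log-Gaussian texture field with a controllable
  correlation length (intratumoral heterogeneity),
* a uniform multiplicative uptake drift with time post-injection
  (``1 + uptake_slope * dt / 30 min``) and an optional drift of the
  texture amplitude (heterogeneity change),
* day-specific multiplicative test-retest noise (one lognormal factor per
  lesion and day, shared by both uptake times of that day) and an optional
  per-scan noise term,
* Gaussian point-spread-function smoothing of the composed volume,
  emulating reconstruction variants of different resolution.

All randomness is drawn from counter-derived generator streams keyed by
(master seed, role, patient, lesion, day, time), so output is reproducible
and stable under re-ordering of the generation loop.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .delineation import SeedRegion
from .io import SUVVolume, write_seed_regions, write_suv_volume

__all__ = [
    "StudyDesign",
    "LesionSpec",
    "SyntheticStudy",
    "generate_lesion",
    "generate_study",
    "random_lesion_specs",
    "write_study",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# stream role tags
_TEXTURE, _DAY_NOISE, _SCAN_NOISE, _PLACEMENT = 1, 2, 3, 4


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(k) for k in key]])
    )


@dataclass(frozen=True)
class StudyDesign:
    """Geometry and acquisition schedule of a synthetic study."""

    n_patients: int = 10
    lesions_per_patient: tuple[int, int] = (1, 10)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 4.0
    uptake_times_min: tuple[float, float] = (60.0, 90.0)
    n_days: int = 2
    psf_fwhm_mm: float = 5.0
    background_suv: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        lo, hi = self.lesions_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("invalid lesions_per_patient range")
        if any(np.diff(self.uptake_times_min) <= 0):
            raise ValueError("uptake times must be strictly increasing")
        if self.n_days < 2:
            raise ValueError("a test-retest design needs at least 2 days")
        if self.voxel_size_mm <= 0 or self.background_suv <= 0:
            raise ValueError("voxel size and background SUV must be positive")

    @property
    def days(self) -> range:
        return range(1, self.n_days + 1)


@dataclass(frozen=True)
class LesionSpec:
    """Parameters of one synthetic lesion.

    ``uptake_slope`` and ``heterogeneity_slope`` are fractional changes per
    30 min of additional uptake time; ``trt_noise_cv`` is the day-to-day
    coefficient of variation of the lesion's uptake; ``scan_noise_cv`` adds
    an independent per-scan component (0 = the pure day-noise model).
    """

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    peak_suv: float
    heterogeneity_amplitude: float = 0.0
    texture_correlation_mm: float = 8.0
    uptake_slope: float = 0.0
    heterogeneity_slope: float = 0.0
    trt_noise_cv: float = 0.0
    scan_noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_suv <= 0:
            raise ValueError("peak_suv must be positive")
        if any(s <= 0 for s in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")
        if self.heterogeneity_amplitude < 0 or self.trt_noise_cv < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.texture_correlation_mm <= 0:
            raise ValueError("texture correlation length must be positive")


@dataclass
class SyntheticStudy:
    """Volumes, seed regions and ground truth of one simulated study."""

    design: StudyDesign
    specs: dict[int, list[LesionSpec]]
    volumes: dict[tuple[int, int, float], SUVVolume]  # (patient, day, time_min)
    seeds: dict[tuple[int, int], SeedRegion]  # (patient, lesion)
    ground_truth: pd.DataFrame


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative noise with the requested CV."""
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(sigma * rng.standard_normal() - 0.5 * sigma * sigma))


def _falloff(r: np.ndarray, core: float = 0.75) -> np.ndarray:
    """Radial profile: 1 on the plateau, cosine roll-off to 0 at r = 1."""
    f = np.zeros_like(r)
    f[r <= core] = 1.0
    ramp = (r > core) & (r < 1.0)
    f[ramp] = 0.5 * (1.0 + np.cos(np.pi * (r[ramp] - core) / (1.0 - core)))
    return f


def _patch_slices(
    spec: LesionSpec, design: StudyDesign, margin_vox: int = 1
) -> tuple[slice, ...]:
    h = design.voxel_size_mm
    sl = []
    for a in range(3):
        lo = int(np.floor((spec.center_mm[a] - spec.semi_axes_mm[a]) / h - 0.5)) - margin_vox
        hi = int(np.ceil((spec.center_mm[a] + spec.semi_axes_mm[a]) / h - 0.5)) + 1 + margin_vox
        if lo < 0 or hi > design.grid_shape[a]:
            raise ValueError(
                f"lesion at {spec.center_mm} mm does not fit in the grid "
                f"(axis {a}: voxels [{lo}, {hi}) vs size {design.grid_shape[a]})"
            )
        sl.append(slice(lo, hi))
    return tuple(sl)


def _ellipsoid_r(spec: LesionSpec, design: StudyDesign, sl) -> np.ndarray:
    """Normalized ellipsoidal radius at voxel centers of the patch."""
    h = design.voxel_size_mm
    axes = [
        (np.arange(s.start, s.stop) + 0.5) * h - c
        for s, c in zip(sl, spec.center_mm)
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum((g / a) ** 2 for g, a in zip(grids, spec.semi_axes_mm)))


def generate_lesion(
    spec: LesionSpec,
    design: StudyDesign,
    day: int,
    time_idx: int,
    patient: int = 0,
    lesion: int = 0,
    smooth: bool = False,
) -> tuple[np.ndarray, tuple[slice, ...]]:
    """One lesion's SUV field at a given (day, uptake time).

    Returns the patch (zero outside the ellipsoid support) and the
    half-open grid slices it occupies.  The texture field is fixed per
    lesion (same realization for every day and time); only its amplitude
    drifts with uptake time.  With ``smooth=True`` the patch itself is
    convolved with the design's PSF; study composition leaves patches raw
    and smooths the assembled volume instead.
    """
    dt = design.uptake_times_min[time_idx] - design.uptake_times_min[0]
    sl = _patch_slices(spec, design)
    r = _ellipsoid_r(spec, design, sl)
    f = _falloff(r)

    amp = spec.heterogeneity_amplitude * max(
        0.0, 1.0 + spec.heterogeneity_slope * dt / 30.0
    )
    if amp > 0:
        rng = _stream(design.rng_seed, _TEXTURE, patient, lesion)
        white = rng.standard_normal(f.shape)
        sigma_vox = spec.texture_correlation_mm * _FWHM_TO_SIGMA / design.voxel_size_mm
        g = ndimage.gaussian_filter(white, sigma_vox)
        sd = g.std()
        if sd > 0:
            g = (g - g.mean()) / sd
        texture = np.exp(amp * g - 0.5 * amp * amp)
    else:
        texture = 1.0

    scale = 1.0 + spec.uptake_slope * dt / 30.0
    day_factor = _lognormal_factor(
        _stream(design.rng_seed, _DAY_NOISE, patient, lesion, day), spec.trt_noise_cv
    )
    scan_factor = _lognormal_factor(
        _stream(design.rng_seed, _SCAN_NOISE, patient, lesion, day, time_idx),
        spec.scan_noise_cv,
    )

    patch = spec.peak_suv * f * texture * scale * day_factor * scan_factor
    if smooth and design.psf_fwhm_mm > 0:
        patch = ndimage.gaussian_filter(
            patch, design.psf_fwhm_mm * _FWHM_TO_SIGMA / design.voxel_size_mm
        )
    return patch, sl


def _check_overlap(specs: list[LesionSpec], design: StudyDesign, patient: int) -> None:
    for (i, a), (j, b) in itertools.combinations(enumerate(specs), 2):
        sla = _patch_slices(a, design, margin_vox=0)
        slb = _patch_slices(b, design, margin_vox=0)
        inter = tuple(
            slice(max(x.start, y.start), min(x.stop, y.stop)) for x, y in zip(sla, slb)
        )
        if any(s.stop <= s.start for s in inter):
            continue
        ra = _ellipsoid_r(a, design, inter)
        rb = _ellipsoid_r(b, design, inter)
        if np.any((ra < 1.0) & (rb < 1.0)):
            raise ValueError(
                f"lesions {i} and {j} of patient {patient} overlap"
            )


def generate_study(
    design: StudyDesign, lesion_specs: dict[int, list[LesionSpec]]
) -> SyntheticStudy:
    """Assemble all (patient, day, time) volumes plus ground truth.

    Lesion fields are composed onto the uniform background by voxelwise
    maximum, then the whole volume is smoothed with the design's PSF.
    Overlapping lesions of one patient are rejected, naming the pair.
    """
    for p, specs in lesion_specs.items():
        for spec in specs:
            if spec.peak_suv <= design.background_suv:
                raise ValueError(
                    f"patient {p}: lesion peak SUV {spec.peak_suv} must exceed "
                    f"background {design.background_suv}"
                )
        _check_overlap(specs, design, p)

    sigma_vox = design.psf_fwhm_mm * _FWHM_TO_SIGMA / design.voxel_size_mm
    spacing = (design.voxel_size_mm,) * 3
    volumes: dict[tuple[int, int, float], SUVVolume] = {}
    seeds: dict[tuple[int, int], SeedRegion] = {}
    gt_rows = []

    for p, specs in lesion_specs.items():
        for l, spec in enumerate(specs):
            sl = _patch_slices(spec, design)
            seeds[(p, l)] = SeedRegion(
                bbox=np.array([[s.start, s.stop] for s in sl])
            )
            t_last = design.uptake_times_min[-1] - design.uptake_times_min[0]
            gt_rows.append(
                {
                    "patient": p,
                    "lesion": l,
                    "peak_suv": spec.peak_suv,
                    "uptake_scale_late": 1.0 + spec.uptake_slope * t_last / 30.0,
                    "heterogeneity_direction": float(np.sign(spec.heterogeneity_slope)),
                    "trt_noise_cv": spec.trt_noise_cv,
                }
            )
        for day in design.days:
            for t_idx, t_min in enumerate(design.uptake_times_min):
                vol = np.full(design.grid_shape, design.background_suv, dtype=np.float64)
                for l, spec in enumerate(specs):
                    patch, sl = generate_lesion(
                        spec, design, day, t_idx, patient=p, lesion=l
                    )
                    vol[sl] = np.maximum(vol[sl], patch)
                if sigma_vox > 0:
                    vol = ndimage.gaussian_filter(vol, sigma_vox)
                volumes[(p, day, float(t_min))] = SUVVolume(
                    values=vol, voxel_size_mm=spacing
                )

    gt = pd.DataFrame(gt_rows)
    return SyntheticStudy(
        design=design,
        specs=lesion_specs,
        volumes=volumes,
        seeds=seeds,
        ground_truth=gt,
    )


def random_lesion_specs(
    design: StudyDesign,
    peak_suv_range: tuple[float, float] = (6.0, 20.0),
    semi_axes_range_mm: tuple[float, float] = (10.0, 18.0),
    heterogeneity_amplitude: float = 0.3,
    texture_correlation_mm: float = 8.0,
    uptake_slope: float = 0.0,
    heterogeneity_slope: float = 0.0,
    trt_noise_cv: float = 0.1,
    scan_noise_cv: float = 0.0,
    edge_margin_mm: float = 12.0,
    max_tries: int = 500,
) -> dict[int, list[LesionSpec]]:
    """Draw per-patient lesion specs with non-overlapping random placement.

    Lesion counts are uniform over the design's ``lesions_per_patient``
    range; peaks and semi-axes are uniform over the given ranges (defaults
    emulate lesions with relatively high FDG uptake on a 1.5 g/mL
    background).  Placement is by rejection sampling with a safety gap
    between ellipsoid supports.
    """
    rng = _stream(design.rng_seed, _PLACEMENT)
    extent = np.asarray(design.grid_shape) * design.voxel_size_mm
    specs: dict[int, list[LesionSpec]] = {}
    for p in range(design.n_patients):
        n = int(rng.integers(design.lesions_per_patient[0], design.lesions_per_patient[1] + 1))
        placed: list[LesionSpec] = []
        for _ in range(n):
            for _try in range(max_tries):
                axes = tuple(rng.uniform(*semi_axes_range_mm, size=3))
                lo = np.asarray(axes) + edge_margin_mm
                hi = extent - lo
                if np.any(hi <= lo):
                    raise ValueError("grid too small for the requested lesion size")
                center = tuple(rng.uniform(lo, hi))
                ok = all(
                    np.linalg.norm(np.asarray(center) - np.asarray(q.center_mm))
                    > max(axes) + max(q.semi_axes_mm) + 4.0
                    for q in placed
                )
                if ok:
                    placed.append(
                        LesionSpec(
                            center_mm=center,
                            semi_axes_mm=axes,
                            peak_suv=float(rng.uniform(*peak_suv_range)),
                            heterogeneity_amplitude=heterogeneity_amplitude,
                            texture_correlation_mm=texture_correlation_mm,
                            uptake_slope=uptake_slope,
                            heterogeneity_slope=heterogeneity_slope,
                            trt_noise_cv=trt_noise_cv,
                            scan_noise_cv=scan_noise_cv,
                        )
                    )
                    break
            else:
                raise ValueError(
                    f"could not place {n} non-overlapping lesions for patient {p}"
                )
        specs[p] = placed
    return specs


def write_study(study: SyntheticStudy, outdir) -> None:
    """Persist a study: NIfTI volume per (patient, day, time), JSON seed
    sidecar, ground-truth CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (p, day, t), vol in study.volumes.items():
        write_suv_volume(vol, outdir / f"pat{p:02d}_day{day}_t{int(t)}min.nii.gz")
    write_seed_regions(
        {f"p{p}_l{l}": seed.bbox for (p, l), seed in study.seeds.items()},
        outdir / "seed_regions.json",
    )
    study.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
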