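# Methods

## Problem and model

`dtpradiomics` studies how PET radiomic features respond to the tracer
uptake interval, and whether that response is large relative to ordinary
test–retest variability. The design it analyzes (and simulates) is a
double-baseline dual-time-point study: each patient is scanned on two
days, and on each day at two post-injection times (≈60 and ≈90 min).
FDG accumulates in metabolically active tissue, so SUV-derived and
texture features drift with uptake time; the day-to-day repeat under
identical conditions calibrates how much drift is "real" signal.

Per feature the analysis computes:

* **Repeatability** — ICC(A,1), the two-way, absolute-agreement,
  single-rating intraclass correlation between the day-1 and day-2
  values at a fixed uptake time, from the ANOVA mean squares
  `(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))` with k = 2 days
  and n lesions. A feature is repeatable if ICC > 0.9 at both times.
* **Time effect** — a paired Wilcoxon signed-rank test between the
  day-1 values at 60 and 90 min, Benjamini–Hochberg corrected across the
  49 features, significant at q < 0.05.
* **Effect size in repeatability units** — the z score
  `z_l = ((RF90 − RF60)_l − mean(TRT60)) / sd(TRT60)`, where
  `TRT60_l = RF60(day 2)_l − RF60(day 1)_l` and the mean/SD run across
  lesions (sample SD). |mean z| ≥ 1 means the uptake-time change exceeds
  day-to-day variability.
* **Use case** — DISCARDED if the ICC gate fails at either time;
  otherwise DTP (dual-time-point: significant **and** |mean z| ≥ 1),
  CS2 (robust cross-sectional: neither), or CS1 (unclear: exactly one of
  the two). Susceptibility uses the magnitude of mean z, so features
  that decrease with time count as susceptible too. Features meeting
  only one of the two susceptibility criteria land in CS1; this reading
  makes the four outcomes a partition and is configurable through the
  `alpha`/`z_gate` arguments.

The Wilcoxon pairs lesions (not patients); lesions from one patient are
treated as independent, which overstates the effective sample size when
lesions within a patient are correlated — a known limitation.

## Feature panel

49 features in 7 classes (6 conventional / 5 shape / 6 histogram /
7 GLCM / 11 GLRLM / 11 GLZLM / 3 NGLDM), the standard panel of
LIFEx-style PET radiomics tools with IBSI-conformant formulas. The class
membership follows that convention where a published member list is not
pinned; identifiers are stable and class-prefixed (e.g. `GLZLM_SZLGE`).

Numerical choices worth knowing:

* **Discretization.** FBW: `level = floor((SUV − min)/W) + 1` with
  W = 0.25 g/mL over 0–60 g/mL (240 levels); out-of-range SUVs clamp
  with a warning (the range is chosen so clamping is unreachable on
  conforming data). FBN: 64 bins over the lesion's own SUVmin–SUVmax;
  the top boundary maps to level 64; a zero-range lesion maps to a
  single level. FBN is invariant to affine rescaling of the lesion's
  intensities, FBW is not — both properties are asserted in tests.
* **Texture matrices.** GLCM and GLRLM pool all 13 unique 3-D unit
  directions (both orientations) into a single matrix before computing
  features, unweighted; per-direction computation is available through
  the `directions` argument. GLZLM zones and the delineation component
  rule both use 26-connectivity. Runs truncate at the mask boundary.
  GLRLM run percentage is normalized by (13 × voxels) so it stays in
  (0, 1] for the pooled matrix.
* **Degenerate inputs.** Single-level ROIs: GLCM correlation := 1,
  histogram skewness/kurtosis/excess := 0, NGLDM coarseness capped at
  1e6 (configurable), NGLDM contrast/busyness := 0. Single-voxel or
  neighbor-less ROIs raise instead of returning junk.
* **Shape.** Surface area comes from a marching-cubes mesh of the mask,
  with a slight Gaussian anti-aliasing (σ = 0.5 voxel) of the binary
  mask before meshing: a raw binary mesh is faceted and overestimates
  the area of smooth objects by ~7%, breaking the sphericity → 1 limit
  for digitized balls. Sphericity is `π^(1/3)(6V)^(2/3)/A`; compacity is
  `A^(3/2)/V` (dimensionless, LIFEx-style). SUVstd uses the population
  convention (ddof = 0).

## Delineation

Three methods, all applied as closed thresholds (`SUV ≥ T`,
configurable) restricted to the 26-connected component containing the
seed region's hottest voxel (so neighboring lesions above the same
threshold are not merged):

* **PCT40** — T = 0.40 × SUVmax, with SUVmax taken inside the seed
  region (not the whole body);
* **SUV4** — T = 4.0 g/mL; lesions with SUVmax < 4 give an empty,
  non-qualifying result rather than an error;
* **contrast** — T = 0.5 × SUVpeak + background. SUVpeak is the mean
  over a 1.0 mL sphere (voxel centers within the sphere radius) placed
  to maximize that mean within the seed region, EANM-style; the
  background is the mean SUV in a one-voxel-pitch-thick shell whose
  Euclidean distance from the 70%-of-SUVmax volume lies in
  [20 mm, 20 mm + pitch), excluding voxels with SUV > 4. "2 cm away" is
  measured from the surface of the 70% volume (nearest-voxel EDT), not
  its centroid.

Only lesions with at least 64 voxels qualify for feature extraction;
smaller ones are logged and excluded.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes,
not PET physics. A lesion is an ellipsoid with a plateau (normalized
radius ≤ 0.75) at `peak_suv` and a cosine roll-off to zero at the
ellipsoid boundary, multiplied by

* a lesion-intrinsic multiplicative texture field
  `exp(a·g − a²/2)` with g a unit-variance Gaussian random field
  (filtered white noise, FWHM = `texture_correlation_mm`) — the field
  realization is fixed per lesion; only its amplitude `a` may drift with
  uptake time (`heterogeneity_slope`);
* a uniform uptake-time scale `1 + uptake_slope·Δt/30 min`;
* one lognormal day factor per (lesion, day) with CV = `trt_noise_cv`,
  shared by both scans of that day — this makes the lesion-mean
  test–retest CV equal `trt_noise_cv` by construction;
* optionally one lognormal per-scan factor (`scan_noise_cv`, default 0)
  so that null simulations have non-degenerate 60-vs-90-min
  differences.

Lesion fields are composed onto a uniform background (default
1.5 g/mL) by voxelwise maximum and the assembled volume is convolved
with an isotropic Gaussian PSF; reconstruction variants are emulated
purely as different PSF FWHMs (a sharper PSF stands for
resolution-modeled reconstruction). Smoothing the composed volume,
rather than each lesion patch, avoids box artifacts at patch borders and
matches how a scanner PSF acts on the whole image.

Randomness comes from counter-derived generator streams keyed by
(master seed, role, patient, lesion, day, time), so studies are
bit-reproducible and insensitive to loop order. Default lesion draws —
peaks uniform in 6–20 g/mL, semi-axes 10–18 mm on a 4 mm grid, 1–10
lesions per patient — emulate lesions with relatively high FDG uptake;
they are plausibility choices, not fitted values.

What the generator does **not** contain: reconstruction/projection
physics, attenuation or scatter, respiratory motion, non-uniform
backgrounds, lesion shape change over time, or within-patient
correlation of lesion parameters. Passing recovery tests therefore show
that the statistical pipeline detects the effects it is built to
detect under its own assumptions — not that those effects are
recoverable from real scanner data.

## Problem sizes in the shipped tests and acceptance script

Texture-matrix oracles run on 100+ random ROIs up to 6×6×6 voxels
against naive triple-loop/flood-fill enumerations. Recovery experiments
use 10 patients with 2–4 lesions each (~30 lesions) on a 48³ grid at
4 mm, drift scenario `uptake_slope = 0.2`, `heterogeneity_slope = 0.3`,
`trt_noise_cv = 0.02`, `scan_noise_cv = 0.01`, PCT40 + FBW + 5 mm PSF;
50 seeds in the test suite, 25 in the acceptance script. The full
clinical-scale 144×144×254 grid remains available through `StudyDesign`. In degenerate
corners of the synthetic model a few features can drop out of a given
study's analysis (e.g. shape features whose test–retest differences are
exactly zero under purely multiplicative noise make sd(TRT60) = 0);
they are excluded with a log entry rather than classified.

## Known limitations

* Lesion-level (not patient-level) pairing in all statistics.
* The exact member list of the conventional and histogram classes
  follows the common LIFEx panel; other tools name or group these
  differently.
* GLCM direction pooling is unweighted; tools that average per-direction
  features instead will differ on anisotropic ROIs.
* The ICC is the single-rating absolute-agreement form only; no
  mixed-effects or Bland–Altman alternatives.
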