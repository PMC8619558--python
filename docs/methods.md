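# Methods

## Problem

Dental cone-beam CT (CBCT) voxel values are historically inconsistent with
the Hounsfield-unit (HU) scale of clinical multidetector CT (MDCT), which
limits their use for jaw-bone density assessment. `decbct` implements a
dual-energy calibration that maps paired low/high-kVp CBCT acquisitions to
HU, plus the analysis pipeline needed to judge how well the calibrated
values agree with MDCT: rigid registration, cylindrical ROI transfer, and
agreement statistics.

## Dual-energy density-line calibration

Let `(L, H)` be a voxel's CT numbers in the low- and high-kVp channels,
each defined as `1000 * (mu - mu_water) / mu_water` at that channel's
effective energy. For a calibration phantom — an acrylic base with
hydroxyapatite (HA) inserts of known HU and an air bore — the per-region
mean pairs `(L_r, H_r)` are nearly collinear in the `(L, H)` plane, because
all regions vary along a single effective density axis. The calibration:

1. **Density line.** Fit a line through the region-mean points. The default
   is total least squares (p0 = centroid, direction = first principal
   component), because both coordinates are noisy measurements; regressing
   high on low is available behind `method="ols_high_on_low"`.
2. **Projection.** Each value pair projects orthogonally onto the line;
   the signed coordinate `t = u . (pair - p0)` is the density surrogate.
   Orthogonal projection is the unique distance-minimizing choice and makes
   the calibration invariant to rotations of the value plane.
3. **HU map.** Ordinary least squares of known HU against `t` over the
   regions with certified HU (air at -1000 plus the HA inserts by default)
   gives `HU = slope * t + intercept`.

Application is strictly voxel-by-voxel and requires the two volumes to
share one grid; the calibration path never resamples.

Self-consistency: if both channels are remapped by one monotone affine map
(pairs stay on a line, projections scale uniformly), refitting on the
remapped phantom reproduces identical HU output. Under channel-*specific*
affine remaps the region samples still calibrate exactly, but off-line
points (e.g. background water, which does not belong to the phantom's
density family) can shift, because anisotropic scaling changes the
orthogonal projection direction. This is a property of any
orthogonal-projection calibration, not an implementation artifact.

## Synthetic phantom and study generator

Volumes are rendered directly in the image domain: each voxel center is
classified against analytic primitives (cylinders, tubes, boxes, horseshoe
arch segments) in painter's order and assigned the material CT number,
optionally plus a radially quadratic bias field (cupping surrogate, off by
default) and i.i.d. Gaussian noise. No projection physics (spectra,
scatter, reconstruction) is simulated.

**Material model.** All phantom/bone materials form a one-parameter
*bone-equivalent density* family `mu_c = kappa_c * rho` with per-channel
constants `kappa_low = 0.30`, `kappa_high = 0.21`, `kappa_mdct = 0.25`
(1/cm per g/cm^3) and `rho = 0` for air; water has its own attenuation
(0.22 / 0.18 / 0.20 1/cm). Consequences, by construction:

* the noiseless `(L, H)` pairs of every family material are exactly
  collinear, passing through air at `(-1000, -1000)`;
* the material's reference HU — its CT number at the MDCT effective
  energy — is exactly affine along that line.

These are precisely the assumptions of the density-line calibration, so on
noiseless renders the calibration is exact to numerical precision, and
every configured corruption (noise, inter-modality bias, misalignment) is
an explicit, recoverable ground truth. A mixture model (water + HA) would
place air off the density line and make even the noiseless calibration
approximate; the family model was chosen so that the exactness of the
*method* and the size of each *corruption* can be tested separately.

Default materials (reference HU): air -1000, acrylic 120, soft tissue 40,
trabecular bone 150, cortical bone 800, HA inserts 250/450/850/1250
(nominal 200/400/800/1200 mg/cm^3). These insert densities and HU are
generator configuration — the ground truth the tests recover — not claims
about any physical phantom.

**Scenes.** The calibration phantom is an acrylic cylinder (radius 40 mm,
height 16 mm) with an air bore and the HA inserts (radius 6 mm) on a
20 mm ring. The jaw scene is a horseshoe cortical shell (arch radius
25 mm, width 9 mm, height 12 mm, cortical thickness 3 mm) around a
trabecular core in soft tissue, with 9 mandible-labelled and 6
maxilla-labelled anchors placed mid-cortex so that the largest clinical
ROI (1.4 mm diameter, 5 mm height) fits in cortical bone with margin.

**Grids.** DE-CBCT: 334 x 334 in-plane at 0.3 mm pitch and 0.3 mm slices;
MDCT: 512 x 512 at 0.332 mm and 0.75 mm slices. Axial extents (64 CBCT /
32 MDCT slices by default) are a package choice sized to cover the scenes;
tests that exercise scale-free properties (determinism, error paths) use
explicitly configured smaller grids.

**Corruptions.** Gaussian noise defaults: SD 30 CT numbers per CBCT
channel, 15 for MDCT — chosen so ROI-mean sampling error is ~1-3 HU at the
default ROI size. The MDCT render multiplies bone materials' CT numbers by
0.95 by default, injecting a known -5% inter-modality bias (DE-CBCT reads
higher, the direction observed clinically) for the agreement stage to
detect. The rigid misalignment (MDCT world -> CBCT world) is stored as the
study's ground-truth transform.

What the generator does **not** emulate: beam hardening and scatter
artifacts, anatomical variability, partial-volume texture at bone
interfaces, or any nonlinearity between the two CBCT channels. Passing
tests therefore demonstrate correctness of the algorithms under the stated
model, not clinical image quality.

## Registration and ROI transfer

Multi-resolution (3-level, shrink 8/4/2) rigid registration via SimpleITK:
mean-squared-error metric (Mattes mutual information available),
regular-step gradient descent over 6 parameters, initialized by aligning
intensity centroids of bone voxels (> 300 CT number). Sampling is dense by
default so repeated runs are bit-identical; stochastic subsampling sits
behind an explicit seed. Failure (no bone voxels, no field-of-view overlap
after initialization) raises a typed error — mirroring clinical pipelines
that exclude failed registrations rather than proceeding.

The estimated transform is reported MDCT-world -> DE-CBCT-world; its exact
algebraic inverse carries ROIs selected in DE-CBCT space into MDCT space.
Rigid transfer of a cylinder maps its center and left-composes its
orientation; height and diameter (hence volume) are unchanged.

ROIs are oriented cylinders (center, height, diameter, three rotation
angles about world x/y/z composed in z*y*x order). Membership is by
voxel-center inclusion on each volume's native grid — no interpolation, no
partial-volume weighting — and the ROI mean is its representative value.
The clinical adjustment ranges (height 4-5 mm, diameter 1.0-1.4 mm, angles
within +/-90 degrees) are validation defaults that warn rather than fail,
since they describe usage, not a constraint of the method.

## Agreement statistics

* **Identity-line bands.** Deviation = `100 * (DECBCT - MDCT) / MDCT`
  (relative to the x-axis value; relative-to-average available). Bands
  `<=10 / 10-15 / 15-20 / >20` percent are closed at the outer edge
  (|dev| = 15 belongs to 10-15). Report percentages are recomputed from
  counts and rounded to one decimal for display only.
* **Normality gate.** Shapiro-Wilk (Royston AS R94 via scipy) on the
  percent differences; the gate passes at p > 0.01. Failing groups are
  flagged but still analyzed.
* **Bland-Altman.** Percent difference `100 * (MDCT - DECBCT) / average`.
  Bias = mean, SD with n-1, limits of agreement = bias +/- 1.96 * SD. The
  bias CI half-width is `t_{0.975, n-1} * s / sqrt(n)`; the CI of each
  agreement limit is reported as the full width `2 * 1.96 * s * sqrt(3/n)`
  (z form; the t variant is available). Counts of points outside the
  limits and outside the outer CI edges are both always reported, since
  "outside the limits" is ambiguous between the two readings.

## Numerical choices and edge cases

* Direction matrices must be orthonormal within 1e-9; voxel indices are
  0-based centers in the DICOM LPS frame.
* Resampling fills out-of-field points with -1000 (air).
* Degenerate fits (coincident region points, < 2 known-HU anchors, zero
  coordinate variance) raise typed errors; single-voxel ROIs report SD 0
  with a warning flag; empty ROIs raise rather than return NaN.
* The density-line direction sign is fixed (positive low-kVp component) so
  serialized models are reproducible; the HU-map slope absorbs the sign.
* All randomness flows from explicit seeds (NumPy `SeedSequence` children
  below 2^31); fixed seeds give bit-identical volumes and reports.

## Known limitations

* Image-domain simulation only; no claim about projection-domain effects.
* Rigid registration only — a sheared cylinder is no longer a cylinder, so
  affine/deformable transfer is out of scope by design.
* Bone-quality classification and automatic anatomical ROI placement are
  out of scope; scenes define named anchors instead.
* Single-frame CT DICOM only; enhanced multi-frame is not read or written.
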