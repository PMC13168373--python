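# Methods

This note documents the models, conventions and numerical choices
behind `spectqc`, and what its synthetic data do and do not emulate.

## Phantoms and coordinates

All geometry lives in a right-handed frame in millimetres with the
origin at the phantom centre; the cylinder axis runs along z. Two
phantoms are modelled:

- a **uniform cylinder** (default 195 mm internal diameter × 211 mm
  internal length, 6.30 L, 800 MBq nominal fill; the bundled study
  conditions use 812 MBq, the assayed fill of such a phantom), used for
  calibration-factor measurements;
- a **NEMA IQ phantom** with six hot spheres and a cold background.
  Sphere diameters default to {13, 17, 22, 28, 37, 60} mm — the
  standard NEMA IEC set with the largest insert extended to 60 mm so
  that the set spans 13–60 mm — at 4 MBq/mL. Centres sit on the
  standard 57.2 mm-radius hexagon in one transaxial plane. The torso
  outline is approximated by a cylindrical envelope (240 mm × 180 mm);
  with a cold background the envelope carries no activity, so its exact
  shape does not affect any estimator. There is no lung insert.

Voxelization uses voxel-centre-in-compartment membership with no
partial-volume weighting: the truth map is deliberately sharp, and all
blur belongs to the simulator. Total voxelized activity converges to
the analytic volume × concentration as spacing decreases (≈0.7% error
at 2 mm for the cylinder, checked in the tests).

## The reconstruction surrogate

The simulator emulates reconstructed SPECT images statistically rather
than physically. Parameters, defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `psf_fwhm` | 12 mm | isotropic Gaussian resolution, typical of medium-energy ¹⁷⁷Lu SPECT |
| `ringing_beta` | 0 | strength of difference-of-Gaussians edge sharpening (0 = pure Gaussian) |
| `ringing_alpha` | 2 | width ratio of the subtracted Gaussian |
| `icf_true` | 20 cps/MBq | ground-truth calibration (typical of a dual-head camera with medium-energy collimation; low-sensitivity systems sit nearer 12) |
| `count_target` | 7 MCts (cylinder) / 3 MCts (NEMA) | fixed-count stop condition; duration = target / (icf_true × total activity) |
| `noise` | poisson | per-voxel Poisson counts |
| `units_out` | counts | counts or Bq/mL output |
| `quant_bias` | 1 | multiplicative error applied in Bq/mL mode |
| `rr_scale` | 1 | projection-scale convention (e.g. ×4) declared in the sidecar |

The effective kernel is `k = (1+β)·G(σ) − β·G(ασ)` with
`σ = fwhm/2.355`. This difference-of-Gaussians form was chosen as the
ringing surrogate — rather than, say, frequency-domain apodization —
because its blurred-sphere radial profile has a closed form (a weighted
superposition of two sphere⊛Gaussian profiles, `spectqc.analytic`),
giving an oracle for both recovery coefficients and the Gibbs metric
that is independent of the voxel pipeline. The kernel integrates to
one, so noiseless counts totals equal icf_true × Δt × activity exactly.

Per-voxel Poisson noise is a deliberate simplification: real
reconstruction noise is spatially correlated and object-dependent (VOI
standard deviations of 13–23% are typical in cylinder images, versus
the ~12% that pure Poisson statistics produce here at 4 mm/7 MCts).
Passing tests therefore demonstrate estimator correctness under the
assumed statistics, not robustness to OSEM noise texture, scatter
residuals or attenuation-correction errors. Projection physics
(collimator response, septal penetration, dead time) is out of scope.

In Bq/mL mode the simulator deliberately miscalibrates the output by
`quant_bias` so the correction-factor path is exercised non-trivially,
mirroring systems whose vendor quantification is off by a constant
factor.

## Calibration factors

The ICF uses the mean counts concentration in a cylindrical VOI of
12 cm diameter × 15 cm length (the largest contour that stays clear of
edge artifacts in the cylinder), centred on the detected phantom
centroid. The centroid is the intensity-weighted centre of mass after
thresholding at 50% of a robust (99.9th-percentile) maximum — no CT or
header positions are needed. Voxel membership is centre-in with no
fractional weighting.

When a reconstruction convention scales counts (declared `rr_scale` in
the sidecar, e.g. ×4 for some resolution-recovery implementations), the
reported ICF is divided by that scale so values are comparable across
systems, and all quantification consistently divides image counts by
the same declared scale. The scale is metadata only; it is never
inferred from value magnitudes.

The expanded-VOI variant integrates all counts in the phantom envelope
dilated by a margin (default 24 mm ≈ 2 × a typical PSF FWHM) and
divides by the total reference activity. It recaptures counts blurred
out of the phantom but absorbs any stray counts in the margin; a test
demonstrates this susceptibility by construction. The dilation-margin
definition was chosen over a threshold-based contour because it is
deterministic and parameter-explicit. On noiseless, background-free,
fully contained simulations the two ICF methods agree within 1% when
the reference activity is the activity actually deposited on the grid.

## Recovery coefficients

Spheres are localized by registering the nominal constellation with a
translation-only grid search (phantoms are scanned axis-aligned, so no
rotation is fitted) over integer-voxel shifts within ±15 mm, maximizing
the summed in-sphere intensity via precomputed sphere-kernel
convolutions; each centre is then refined as the intensity centre of
mass in a ball of radius R + 1 PSF FWHM. Spheres whose peak is below
twice the background median are flagged rather than silently placed.
Sphere VOIs use the theoretical diameters. RC is defined from the
**mean** in-sphere concentration; no max/peak variants are offered.
The cold background is not subtracted (the phantom's background
carries no activity); a warm-background option exists in
`radial_profile` but defaults off.

Numerical caveat: for a *sharp* (unblurred) sphere, a sub-voxel error
in the estimated centre flips boundary voxels and can move the 13 mm
sphere's RC by ~4% at 2 mm voxels. This is a voxelization artifact of
the degenerate no-blur case, not a quantification error, so the
identity check segments at the true centres; all blurred cases use the
full localization chain, where the effect is negligible.

The RC spread statistic is reported in absolute percentage points,
`(max − min) × 100`, at a stated diameter.

## Gibbs-artifact strength

The radial profile of the largest sphere takes one point per voxel
within 1.25 R of the centre (far enough to anchor the background,
short enough to avoid the neighbouring sphere), quantified through the
ICF or CF and normalized so the true in-sphere signal is 1 and the
background 0 — making GA invariant under global image rescaling. A
cubic smoothing spline is fitted with the smoothing parameter chosen by
generalized cross-validation (deterministic; a fixed parameter can be
supplied instead and is logged in the result). Before fitting, voxels
are aggregated into 0.25 mm radial bins with count weights — the
weighted-least-squares equivalent that keeps GCV well-posed on dense
scatters.

`M` is the spline maximum over r ∈ [0, 0.9 R] (the cap excludes the
blur-dominated edge falloff), `m` the minimum over [0, r_M], and
`GA = (M − m)/(M + m)`. A monotone-decreasing profile has its maximum
at r = 0, hence m = M and GA = 0 by construction. This
extremum-identification rule is this package's own operational
definition; it is documented here precisely because published
procedures vary, and both the search cap and the analyzed sphere
diameter are configurable.

## RNC metrology

Readings are background-corrected per reading, decay-corrected to the
session reference time (`A_ref = A(t)·2^{Δt/T½}`, T½ = 6.6443 d for
¹⁷⁷Lu) and averaged; the deviation is the mean against a traceable
reference activity. Sessions default to ≥9 readings spread over hours.

Corrected dial settings null the observed deviation under a pluggable
chamber response model: proportional (reading ∝ dial; `vik202`-style),
inverse-proportional (`crc55tr`-style), or a user-supplied fractional
sensitivity per dial unit. The two named models capture the direction
and magnitude of real factory-to-corrected dial steps for those chamber
types; vendor manuals are not public, hence the pluggable design.
Display conventions (reading multipliers, high-gain settings) are kept
outside the correction arithmetic. One correction step reduces any
±10% bias to below the integer-dial granularity (<0.1% at dial ≈750).

The geometry correction factor is defined as
`(response_clin/true_clin)/(response_ref/true_ref)` — the clinical
geometry's relative response, >1 meaning it reads relatively high, so a
clinical reading is *divided* by the factor. The convention is stated
explicitly because the inverse (multiply-to-correct) convention is
equally common; the CLI and acceptance outputs note which is used.

Uncertainty budgets convert each component to a standard uncertainty
(normal k=1 as-is, normal k=2 halved, rectangular half-width divided by
√3), combine in quadrature and multiply by the coverage factor
(default k=2, ~95%).

## Synthetic multicenter study

`spectqc.study` crosses seven synthetic systems from four scanner
families — high-sensitivity cameras with strong edge ringing,
low-sensitivity cameras without ringing but with a ×4 projection scale,
CZT ring systems, and Bq/mL-native systems with a quantification bias —
with three protocol scenarios (clinical parameters per system versus
family-standard reconstruction parameters). Family parameters are
chosen so that standardized reconstruction clusters each family into a
narrow recovery band while families remain separated, the qualitative
structure such multicenter comparisons exhibit; the specific synthetic
values are illustrative, not measurements. The default study runs at
4 mm voxels and completes in well under a minute per scenario on one
CPU; all seeds, parameters and file hashes are recorded in the run
directory's `index.json`.

## Problem sizes and determinism

Tests and the acceptance script run cylinder analyses at 4 mm voxels
(7 MCts) and oracle comparisons at 2 mm (noiseless) — sizes at which
voxelization errors are comfortably inside the stated tolerances while
a full run stays fast on a single CPU. Every stochastic quantity is
seeded; identical seeds reproduce images, sessions and CSV outputs bit
for bit. Degenerate inputs (zero images, empty VOIs, single-reading
sessions, monotone profiles) return defined values or explicit errors
rather than silent fallbacks.

## Known limitations

- No projection-space physics: scatter, attenuation errors, septal
  penetration and reconstruction-algorithm differences enter only
  through their surrogates (stray-count constructions, the ringing
  kernel, `quant_bias`).
- Poisson voxel noise underestimates the spatial correlation of real
  reconstruction noise.
- The NEMA torso shape is a cylindrical envelope; fine for a cold
  background, inadequate if a warm background were simulated with
  realistic scatter geometry.
- Chamber response models are local linearizations around the current
  dial; large dial excursions or gain-range changes are not modelled.
- NIfTI plus a JSON sidecar is the only on-disk image format; DICOM
  series must be converted upstream.
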