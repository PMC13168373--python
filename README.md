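# spectqc

Quantitative quality control for ¹⁷⁷Lu SPECT/CT imaging: image
calibration factors, sphere recovery coefficients, Gibbs-artifact
metrics and radionuclide-calibrator (RNC) metrology, with a synthetic
phantom simulator so the full analysis chain can be exercised and
validated without scanner data.

## The problem

Radionuclide therapy dosimetry needs SPECT images that report absolute
activity. In practice this rests on a chain of calibrations that differs
between hospitals: the well-type ionization chamber ("dose calibrator")
that assays the administered activity, the scanner's count-to-activity
calibration, and the reconstruction settings that determine how much of
a small object's activity is actually recovered. `spectqc` implements
the standard phantom-based QC analyses for this chain:

- **Image calibration factor** (ICF, cps/MBq), from a uniformly filled
  cylinder: `ICF = [C] / (Δt · [A_C])`, with `[C]` the counts
  concentration in a cylindrical VOI (default 12 cm × 15 cm) well inside
  the phantom, `Δt` the acquisition duration and `[A_C]` the reference
  activity concentration from gamma-counter samples. An expanded-VOI
  variant (all counts from the phantom plus a blur margin) is provided
  for comparison.
- **Correction factor** (CF, MBq/MBq) for systems whose images are
  already expressed in Bq/mL: `CF = [A_meas,C] / [A_C]` in the same VOI.
- **Recovery coefficients** (RC) of the six hot spheres of a NEMA IQ
  phantom: `RC_i = [A_i] / [A_N]`, with `[A_i] = [C_i]/(ICF·Δt)` for
  counts images or `[A_i] = [A_meas,i]/CF` for Bq/mL images, the sphere
  VOIs segmented at their theoretical diameters after image-based
  localization. Recovery bands (mean/min/max across systems) and RC
  spreads summarize multicenter variability.
- **Gibbs-artifact strength** `GA = (M − m)/(M + m)` of the largest
  sphere, from the extrema of a smoothing spline fitted to the
  normalized radial profile — a measure of the edge ringing that
  resolution-recovery reconstruction produces.
- **RNC metrology**: session statistics (background correction, decay
  correction to a reference time, averaging), corrected dial settings
  for proportional- and inverse-responding chambers, geometry correction
  factors between vial types, and GUM-style expanded uncertainty budgets
  (quadrature of standard uncertainties, coverage factor *k*).
- **System characterization**: parallel-hole collimator geometric
  sensitivity and resolution (Anger relations with septal-penetration
  corrected hole length) and crystal interaction-probability ratios.

A simulator (`spectqc.simulate`) generates "reconstructed" phantom
images with a Gaussian point-spread function, optional
difference-of-Gaussians edge ringing, a known true calibration factor,
count-targeted acquisition durations and Poisson noise — in counts or
Bq/mL output — plus RNC reading sessions and gamma-counter samples, so
every estimator above can be tested against known ground truth and
against closed-form oracles (`spectqc.analytic`).

## Worked example

```python
import spectqc as sq
from spectqc.simulate import ReconstructionModel, simulate_phantom

# calibration cylinder: 6.3 L filled with 812 MBq, imaged by a system
# with a true calibration of 20 cps/MBq to a 7 MCts count target
cyl = sq.PhantomSpec.uniform_cylinder(total_activity=812.0)
model = ReconstructionModel(psf_fwhm=12.0, icf_true=20.0,
                            count_target=7e6, noise="poisson", seed=1)
img = simulate_phantom(cyl, model, spacing=4.0)
voi = sq.place_cylinder_voi(img, cyl)
icf = sq.compute_icf(img, voi, cyl.cylinder_concentration)
print(f"ICF = {icf.icf:.2f} cps/MBq over {icf.voi_voxel_count} voxels")

# NEMA phantom: six hot spheres at 4 MBq/mL, cold background
nema = sq.PhantomSpec.nema_iq()
nimg = simulate_phantom(nema, ReconstructionModel(
    psf_fwhm=12.0, icf_true=20.0, count_target=3e6, noise="poisson",
    seed=2), spacing=4.0)
locs = sq.locate_spheres(nimg, nema, psf_fwhm=12.0)
masks = sq.segment_spheres([l.center for l in locs],
                           [l.diameter for l in locs], nimg.grid)
curve = sq.compute_recovery_curve(nimg, masks,
                                  [l.diameter for l in locs], icf, 4.0)
for m in curve.measurements:
    print(f"  {m.diameter:4.0f} mm  RC = {m.rc:.3f}")
```

prints

```
ICF = 19.99 cps/MBq over 27208 voxels
    13 mm  RC = 0.230
    17 mm  RC = 0.380
    22 mm  RC = 0.491
    28 mm  RC = 0.577
    37 mm  RC = 0.677
    60 mm  RC = 0.797
```

The recovered ICF matches the simulator's true 20 cps/MBq to 0.05%, and
the recovery coefficients rise with sphere diameter as partial-volume
losses shrink: the 13 mm sphere recovers only ~25% of its true
concentration under a 12 mm FWHM PSF while the 60 mm sphere recovers
~80%, in agreement with the closed-form blurred-sphere values
(`spectqc.analytic_recovery_coefficient`).

A command-line interface wraps the same operations
(`spectqc simulate | icf | cf | rc | gibbs | rnc | study | report`); see
`spectqc --help`.

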