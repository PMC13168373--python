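"""Synthetic "reconstructed" SPECT images and measurement sessions.

The simulator emulates the statistical structure that the downstream
analysis assumes, without modelling projection physics:

* resolution blur as an isotropic Gaussian point-spread function;
* optional edge ringing (the overshoot/undershoot that resolution
  recovery produces at sharp edges) as a difference-of-Gaussians
  sharpening kernel, chosen because its blurred-sphere profile has a
  closed form (see :mod:`spectqc.analytic`);
* a calibration scale icf_true (cps/MBq) converting activity to
  expected reconstructed counts;
* acquisition durations chosen to hit a fixed total-count target
  (7 MCts for the calibration cylinder, 3 MCts for the NEMA phantom);
* per-voxel Poisson noise as a surrogate for reconstruction noise;
* either counts output (optionally carrying a resolution-recovery
  projection scale, e.g. x4) or Bq/mL output with a deliberate
  multiplicative quantification bias so the correction-factor path is
  exercised non-trivially.

It also generates radionuclide-calibrator reading sessions (bias,
jitter, background, radioactive decay) and gamma-counter samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
from scipy.ndimage import gaussian_filter

from .analytic import FWHM_TO_SIGMA
from .images import VoxelImage
from .phantoms import GridSpec, PhantomSpec, voxelize
from .rnc import LU177_HALF_LIFE_DAYS, RNCReading, RNCSession, decay_correct

__all__ = [
    "ReconstructionModel",
    "RNCModel",
    "effective_kernel",
    "apply_psf",
    "duration_for_count_target",
    "simulate_reconstruction",
    "simulate_phantom",
    "simulate_rnc_session",
    "simulate_gamma_samples",
]


@dataclass(frozen=True)
class ReconstructionModel:
    """Parameters of one synthetic SPECT system / protocol.

    Exactly one of ``count_target`` and ``duration`` must be set: the
    former mimics count-targeted acquisitions (duration derived from the
    phantom activity), the latter fixes the duration directly.
    """

    psf_fwhm: float = 12.0           # mm, isotropic Gaussian FWHM
    ringing_beta: float = 0.0        # DoG sharpening strength, >= 0
    ringing_alpha: float = 2.0       # DoG width ratio, > 1
    icf_true: float = 20.0           # cps/MBq ground-truth calibration
    quant_bias: float = 1.0          # multiplicative error in Bq/mL mode
    count_target: float | None = 7e6
    duration: float | None = None    # s
    noise: str = "poisson"           # none | poisson
    seed: int = 0
    units_out: str = "counts"        # counts | Bq/mL
    rr_scale: float = 1.0            # projection scale convention (e.g. 4)
    system_id: str = ""
    scenario: str = ""

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.ringing_beta < 0:
            raise ValueError("ringing_beta must be >= 0")
        if self.ringing_alpha <= 1:
            raise ValueError("ringing_alpha must be > 1")
        if self.icf_true <= 0:
            raise ValueError("icf_true must be positive")
        if (self.count_target is None) == (self.duration is None):
            raise ValueError("set exactly one of count_target and duration")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.units_out not in ("counts", "Bq/mL"):
            raise ValueError(f"unknown output units {self.units_out!r}")


def effective_kernel(model: ReconstructionModel):
    """1-D profile of the effective PSF along any axis:
    k(x) = (1+beta) G(x; sigma) - beta G(x; alpha sigma).

    The 3-D kernel is the same combination of two isotropic Gaussians;
    it integrates to one, and beta = 0 reduces it to a pure Gaussian.
    """
    if model.psf_fwhm <= 0:
        raise ValueError("effective_kernel requires psf_fwhm > 0")
    sigma = model.psf_fwhm / FWHM_TO_SIGMA
    beta, alpha = model.ringing_beta, model.ringing_alpha

    def kernel(x):
        x = np.asarray(x, dtype=float)
        g1 = np.exp(-(x**2) / (2 * sigma**2)) / (sigma * math.sqrt(2 * math.pi))
        if beta == 0.0:
            return g1
        s2 = alpha * sigma
        g2 = np.exp(-(x**2) / (2 * s2**2)) / (s2 * math.sqrt(2 * math.pi))
        return (1.0 + beta) * g1 - beta * g2

    return kernel


def apply_psf(values: np.ndarray, spacing, fwhm: float,
              beta: float = 0.0, alpha: float = 2.0) -> np.ndarray:
    """Convolve a volume with the effective kernel (two separable
    Gaussian passes combined).  fwhm = 0 is the identity."""
    if fwhm == 0:
        return values
    if beta < 0 or alpha <= 1:
        raise ValueError("require beta >= 0 and alpha > 1")
    sigma = np.asarray([fwhm / FWHM_TO_SIGMA / s for s in spacing])
    g1 = gaussian_filter(values, sigma, mode="constant")
    if beta == 0.0:
        return g1
    g2 = gaussian_filter(values, alpha * sigma, mode="constant")
    return (1.0 + beta) * g1 - beta * g2


def duration_for_count_target(truth_total_activity: float, icf_true: float,
                              target: float) -> float:
    """Acquisition duration (s) needed for the expected total counts to
    reach the target, given the total activity (MBq) and true
    calibration (cps/MBq)."""
    if truth_total_activity <= 0:
        raise ValueError("total activity must be positive")
    if icf_true <= 0 or target <= 0:
        raise ValueError("icf_true and target must be positive")
    return target / (icf_true * truth_total_activity)


def simulate_reconstruction(truth: VoxelImage | np.ndarray,
                            model: ReconstructionModel,
                            grid: GridSpec | None = None) -> VoxelImage:
    """Turn a ground-truth concentration map (MBq/mL) into a synthetic
    reconstructed image.

    Expected counts per voxel are (truth (*) kernel) x icf_true x
    duration x voxel volume; Poisson noise is applied if enabled.  In
    counts mode, voxel values additionally carry the declared rr_scale;
    in Bq/mL mode, counts are converted back to concentration and the
    model's quant_bias is applied.
    """
    if isinstance(truth, VoxelImage):
        if truth.units != "MBq/mL":
            raise ValueError("truth map must be in MBq/mL")
        values, grid = truth.values, truth.grid
    else:
        if grid is None:
            raise ValueError("grid required when truth is a bare array")
        values = np.asarray(truth, dtype=float)
        if values.shape != tuple(grid.shape):
            raise ValueError("truth array does not match the grid")

    vox_mL = grid.voxel_volume_mL
    total_activity = float(values.sum()) * vox_mL
    if model.duration is not None:
        duration = model.duration
    else:
        duration = duration_for_count_target(total_activity, model.icf_true,
                                             model.count_target)

    blurred = apply_psf(values, grid.spacing, model.psf_fwhm,
                        model.ringing_beta, model.ringing_alpha)
    expected = blurred * model.icf_true * duration * vox_mL
    if model.noise == "poisson":
        rng = np.random.default_rng(model.seed)
        counts = rng.poisson(np.clip(expected, 0, None)).astype(float)
    else:
        counts = expected

    if model.units_out == "counts":
        out = counts * model.rr_scale
        return VoxelImage(values=out, spacing=grid.spacing, units="counts",
                          duration=duration, rr_scale=model.rr_scale,
                          system_id=model.system_id, scenario=model.scenario,
                          origin=grid.origin)
    conc = counts / (model.icf_true * duration * vox_mL)  # MBq/mL
    out = conc * model.quant_bias * 1e6                   # Bq/mL
    return VoxelImage(values=out, spacing=grid.spacing, units="Bq/mL",
                      duration=duration, system_id=model.system_id,
                      scenario=model.scenario, origin=grid.origin)


def simulate_phantom(spec: PhantomSpec, model: ReconstructionModel,
                     spacing: float = 4.0, margin: float = 30.0) -> VoxelImage:
    """Voxelize a phantom and simulate its reconstruction in one step."""
    grid = GridSpec.for_phantom(spec, spacing, margin=margin)
    return simulate_reconstruction(voxelize(spec, grid), model, grid)


# --- measurement-session simulation -------------------------------------

@dataclass(frozen=True)
class RNCModel:
    """Generative model for a calibrator reading session: a vial of
    known activity at the reference time, read n times over several
    hours with a fractional response bias, multiplicative jitter and an
    additive background, decaying physically between readings."""

    true_activity_at_ref: float          # MBq
    half_life: float = LU177_HALF_LIFE_DAYS  # days
    bias: float = 0.0                    # fractional response error
    jitter_sd: float = 0.004             # fractional, per reading
    background: float = 0.0              # MBq
    n_readings: int = 9
    reading_times: tuple[datetime, ...] | None = None
    ref_time: datetime = datetime(2024, 1, 1, 8, 0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_activity_at_ref <= 0:
            raise ValueError("true activity must be positive")
        if self.half_life <= 0:
            raise ValueError("half-life must be positive")
        if self.n_readings < 1:
            raise ValueError("need at least one reading")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def simulate_rnc_session(model: RNCModel, protocol: str = "factory",
                         chamber_model: str = "generic",
                         dial_setting: int = 0,
                         vial_geometry: str = "reference") -> RNCSession:
    """Draw one reading session: reading_i = A(t_i)(1+bias)(1+eps_i) +
    background, with eps_i ~ Normal(0, jitter_sd) and A(t) the
    physically decayed activity."""
    rng = np.random.default_rng(model.seed)
    if model.reading_times is not None:
        times = list(model.reading_times)
    else:
        # readings spread over several hours, ~30 min apart
        times = [model.ref_time + timedelta(minutes=30 * i)
                 for i in range(model.n_readings)]
    readings = []
    for t in times:
        decayed = decay_correct(model.true_activity_at_ref, model.ref_time, t,
                                model.half_life)
        eps = rng.normal(0.0, model.jitter_sd) if model.jitter_sd > 0 else 0.0
        raw = decayed * (1.0 + model.bias) * (1.0 + eps) + model.background
        readings.append(RNCReading(timestamp=t, raw_reading=raw,
                                   background=model.background))
    return RNCSession(readings=readings, ref_time=model.ref_time,
                      protocol=protocol, chamber_model=chamber_model,
                      dial_setting=dial_setting, vial_geometry=vial_geometry)


def simulate_gamma_samples(concentration: float, n: int = 3,
                           cv: float = 0.01, seed: int = 0) -> np.ndarray:
    """Gamma-counter aliquot concentrations: n normal draws around the
    true concentration with the stated coefficient of variation."""
    if n < 1:
        raise ValueError("need at least one sample")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0 or concentration == 0:
        return np.full(n, float(concentration))
    rng = np.random.default_rng(seed)
    return concentration * (1.0 + rng.normal(0.0, cv, size=n))
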