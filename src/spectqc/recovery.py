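"""Sphere localization, segmentation and recovery coefficients.

The recovery coefficient of sphere i is

    RC_i = [A_i] / [A_N]

with [A_N] the true activity concentration of the sphere fill and
[A_i] the mean concentration measured in the sphere VOI, obtained
either from counts images via the cylinder-derived ICF,
[A_i] = [C_i]/(ICF dt), or from Bq/mL images via the correction
factor, [A_i] = [A_meas,i]/CF.  Spheres are segmented at their
theoretical diameters (voxel-centre-in-sphere), after locating the
sphere constellation by a translation-only grid search (phantoms are
scanned axis-aligned) followed by a per-sphere centre-of-mass
refinement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .calibration import CFResult, ICFResult
from .images import VoxelImage
from .phantoms import PhantomSpec

__all__ = [
    "SphereLocation",
    "SphereMeasurement",
    "RecoveryCurve",
    "locate_spheres",
    "segment_spheres",
    "compute_recovery_curve",
    "recovery_band",
    "rc_spread",
]


@dataclass(frozen=True)
class SphereLocation:
    center: tuple[float, float, float]  # mm, world frame
    diameter: float
    flagged: bool = False  # signal indistinguishable from background


@dataclass(frozen=True)
class SphereMeasurement:
    diameter: float                    # mm
    measured_concentration: float      # MBq/mL ([A_i])
    activity_concentration: float      # MBq/mL true fill ([A_N])
    rc: float                          # [A_i]/[A_N]


@dataclass(frozen=True)
class RecoveryCurve:
    measurements: tuple[SphereMeasurement, ...]
    ref_concentration: float  # MBq/mL
    system_id: str = ""
    scenario: str = ""

    def __post_init__(self) -> None:
        ms = tuple(sorted(self.measurements, key=lambda m: m.diameter))
        d = [m.diameter for m in ms]
        if len(set(d)) != len(d):
            raise ValueError("duplicate sphere diameters in curve")
        object.__setattr__(self, "measurements", ms)

    @property
    def diameters(self) -> np.ndarray:
        return np.array([m.diameter for m in self.measurements])

    @property
    def rcs(self) -> np.ndarray:
        return np.array([m.rc for m in self.measurements])


def _world_to_index(center, grid) -> np.ndarray:
    axes = grid.axes()
    return np.array([(c - a[0]) / s for c, a, s in
                     zip(center, axes, grid.spacing)])


def _sphere_kernel(radius: float, spacing) -> np.ndarray:
    half = [int(np.ceil(radius / s)) for s in spacing]
    ax = [(np.arange(-h, h + 1) * s) for h, s in zip(half, spacing)]
    d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
          + ax[2][None, None, :] ** 2)
    return (d2 <= radius**2).astype(float)


def locate_spheres(image: VoxelImage, spec: PhantomSpec,
                   psf_fwhm: float = 12.0,
                   max_shift: float = 15.0) -> list[SphereLocation]:
    """Find sphere centres in an image of the NEMA phantom.

    The nominal constellation is first registered by the rigid
    translation (grid search over integer-voxel shifts within
    ``max_shift`` mm) maximizing the summed in-sphere intensity; each
    sphere centre is then refined as the intensity centre of mass in a
    search ball of radius sphere-radius + one PSF FWHM.  Spheres whose
    peak is below twice the background level are flagged rather than
    silently placed.
    """
    if spec.kind != "nema_iq" or not spec.spheres:
        raise ValueError("locate_spheres needs a NEMA phantom spec with spheres")
    grid = image.grid
    vals = image.values
    # per-sphere in-sphere intensity sum as a function of centre position
    convs = [fftconvolve(vals, _sphere_kernel(s.radius, grid.spacing),
                         mode="same") for s in spec.spheres]
    nominal_idx = [_world_to_index(s.center, grid) for s in spec.spheres]
    steps = [int(np.floor(max_shift / s)) for s in grid.spacing]
    best_score, best_shift = -np.inf, (0, 0, 0)
    for shift in itertools.product(*(range(-k, k + 1) for k in steps)):
        score = 0.0
        ok = True
        for conv, idx in zip(convs, nominal_idx):
            j = tuple(int(round(c)) + s for c, s in zip(idx, shift))
            if any(q < 0 or q >= n for q, n in zip(j, vals.shape)):
                ok = False
                break
            score += conv[j]
        if ok and score > best_score:
            best_score, best_shift = score, shift
    shift_mm = np.array(best_shift) * np.array(grid.spacing)

    # background level: robust median outside the (shifted) spheres
    axes = grid.axes()
    X = axes[0][:, None, None]
    Y = axes[1][None, :, None]
    Z = axes[2][None, None, :]
    sphere_union = np.zeros(vals.shape, dtype=bool)
    for s in spec.spheres:
        c = np.array(s.center) + shift_mm
        sphere_union |= ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
                         <= (s.radius + psf_fwhm) ** 2)
    background = float(np.median(vals[~sphere_union])) if (~sphere_union).any() else 0.0

    locations = []
    for s in spec.spheres:
        c = np.array(s.center) + shift_mm
        ball = ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
                <= (s.radius + psf_fwhm) ** 2)
        peak = float(vals[ball].max()) if ball.any() else 0.0
        if peak <= 0 or peak < 2.0 * background:
            locations.append(SphereLocation(tuple(c), s.diameter, flagged=True))
            continue
        w = np.clip(vals, 0, None) * ball
        total = w.sum()
        com = np.array([float((w * A).sum()) / total for A in (X, Y, Z)])
        locations.append(SphereLocation(tuple(com), s.diameter, flagged=False))
    return locations


def segment_spheres(centers, diameters, grid) -> list[np.ndarray]:
    """Voxel-centre-in-sphere masks at the theoretical diameters.
    Raises if centres fall outside the grid or masks overlap."""
    axes = grid.axes()
    X = axes[0][:, None, None]
    Y = axes[1][None, :, None]
    Z = axes[2][None, None, :]
    masks = []
    for c, d in zip(centers, diameters):
        for ci, (lo, hi) in zip(c, grid.extent()):
            if ci < lo or ci > hi:
                raise ValueError(f"sphere centre {c} outside the grid")
        masks.append(((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
                     <= (d / 2.0) ** 2)
    counts = np.zeros(grid.shape, dtype=int)
    for m in masks:
        counts += m
    if (counts > 1).any():
        raise ValueError("sphere masks overlap")
    return masks


def mean_concentration(image: VoxelImage, mask: np.ndarray,
                       calib: ICFResult | CFResult) -> float:
    """Mean activity concentration (MBq/mL) in a mask, quantified via
    the ICF (counts images) or the CF (Bq/mL images)."""
    sel = image.values[mask]
    if sel.size == 0:
        raise ValueError("empty mask")
    mean = float(sel.mean())
    if image.units == "counts":
        if not isinstance(calib, ICFResult):
            raise ValueError("counts image requires an ICF calibration")
        if calib.rr_scale != image.rr_scale:
            raise ValueError("rr_scale mismatch between image and calibration")
        c = mean / image.voxel_volume_mL / image.rr_scale
        return c / (calib.icf * image.duration)
    if not isinstance(calib, CFResult):
        raise ValueError("Bq/mL image requires a CF calibration")
    scale = 1e-6 if image.units == "Bq/mL" else 1.0
    return mean * scale / calib.cf


def compute_recovery_curve(image: VoxelImage, masks, diameters,
                           calib: ICFResult | CFResult,
                           ref_concentration: float,
                           system_id: str = "",
                           scenario: str = "") -> RecoveryCurve:
    """Per-sphere RC from mean in-sphere concentration.

    The calibration must come from the cylinder acquired and
    reconstructed under the same conditions as this image.
    """
    if ref_concentration <= 0:
        raise ValueError("reference concentration must be positive")
    measurements = []
    for mask, d in zip(masks, diameters):
        a = mean_concentration(image, mask, calib)
        measurements.append(SphereMeasurement(
            diameter=d, measured_concentration=a,
            activity_concentration=ref_concentration,
            rc=a / ref_concentration))
    return RecoveryCurve(measurements=tuple(measurements),
                         ref_concentration=ref_concentration,
                         system_id=system_id or image.system_id,
                         scenario=scenario or image.scenario)


def recovery_band(curves) -> "pd.DataFrame":
    """Elementwise mean/min/max RC per diameter over a set of curves."""
    import pandas as pd

    curves = list(curves)
    if not curves:
        raise ValueError("need at least one curve")
    d0 = curves[0].diameters
    for c in curves[1:]:
        if not np.array_equal(c.diameters, d0):
            raise ValueError("curves have mismatched sphere diameters")
    rcs = np.vstack([c.rcs for c in curves])
    return pd.DataFrame({
        "diameter_mm": d0,
        "mean": rcs.mean(axis=0),
        "min": rcs.min(axis=0),
        "max": rcs.max(axis=0),
    })


def rc_spread(curves, diameter: float) -> float:
    """Spread of RC across curves at one sphere diameter, in absolute
    percentage points: (max - min) x 100."""
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    vals = []
    for c in curves:
        match = [m.rc for m in c.measurements if m.diameter == diameter]
        if not match:
            raise ValueError(f"diameter {diameter} mm absent from a curve")
        vals.append(match[0])
    return (max(vals) - min(vals)) * 100.0
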