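"""Parametric phantom geometry and voxelization.

Two phantoms are modelled: a uniform activity-filled cylinder used for
system calibration, and a NEMA IEC image-quality phantom carrying six
fillable hot spheres in a cold background compartment.  Both are defined
in a right-handed coordinate frame in millimetres with the origin at the
phantom centre; the cylinder axis and the phantom long axis run along z.

Voxelization uses a voxel-centre-in-compartment membership rule.  No
partial-volume weighting is applied here: resolution blur is the
simulator's job, so the voxelized map is the ground-truth activity
concentration ("truth map") in MBq/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SphereSpec",
    "PhantomSpec",
    "GridSpec",
    "sphere_volume",
    "cylinder_volume",
    "voxelize",
    "NEMA_SPHERE_DIAMETERS",
]

#: Default hot-sphere diameters (mm): the standard NEMA IEC set extended
#: to a 60 mm sphere, spanning 13-60 mm.
NEMA_SPHERE_DIAMETERS = (13.0, 17.0, 22.0, 28.0, 37.0, 60.0)

#: Radius (mm) of the circle on which sphere centres sit in the
#: transaxial plane (standard NEMA IEC arrangement).
_NEMA_RING_RADIUS = 57.2


def sphere_volume(diameter: float) -> float:
    """Volume of a sphere in mL given its diameter in mm (pi*d^3/6)."""
    if diameter <= 0:
        raise ValueError(f"sphere diameter must be positive, got {diameter}")
    return math.pi * diameter**3 / 6.0 / 1000.0


def cylinder_volume(diameter: float, length: float) -> float:
    """Volume of a cylinder in litres given diameter and length in mm."""
    if diameter <= 0 or length <= 0:
        raise ValueError(
            f"cylinder dimensions must be positive, got d={diameter}, L={length}"
        )
    return math.pi * (diameter / 2.0) ** 2 * length / 1e6


@dataclass(frozen=True)
class SphereSpec:
    """A fillable sphere: centre (mm, phantom frame), diameter (mm) and
    activity concentration (MBq/mL)."""

    center: tuple[float, float, float]
    diameter: float
    activity_concentration: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")
        if self.activity_concentration < 0:
            raise ValueError("activity concentration must be >= 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume_mL(self) -> float:
        return sphere_volume(self.diameter)


def default_nema_spheres(
    diameters: tuple[float, ...] = NEMA_SPHERE_DIAMETERS,
    concentration: float = 4.0,
    ring_radius: float = _NEMA_RING_RADIUS,
) -> list[SphereSpec]:
    """Standard hexagonal NEMA IEC sphere arrangement in one transaxial
    plane (z = 0), largest sphere at angle 0, 60 degrees apart."""
    spheres = []
    for i, d in enumerate(sorted(diameters, reverse=True)):
        ang = math.radians(60.0 * i)
        c = (ring_radius * math.cos(ang), ring_radius * math.sin(ang), 0.0)
        spheres.append(SphereSpec(center=c, diameter=d, activity_concentration=concentration))
    return spheres


@dataclass(frozen=True)
class PhantomSpec:
    """Either a uniform cylinder or a NEMA IQ phantom.

    For ``kind="cylinder"`` the cylinder is uniformly filled at
    ``cylinder_concentration``.  For ``kind="nema_iq"`` the cylinder
    dimensions describe the body envelope filled at
    ``background_concentration`` (0 = cold background) and ``spheres``
    carry the hot inserts.
    """

    kind: str  # "cylinder" | "nema_iq"
    cylinder_length: float
    cylinder_diameter: float
    cylinder_concentration: float = 0.0
    spheres: tuple[SphereSpec, ...] = field(default_factory=tuple)
    background_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("cylinder", "nema_iq"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if cylinder_volume(self.cylinder_diameter, self.cylinder_length) <= 0:
            raise ValueError("cylinder volume must be positive")
        spheres = tuple(self.spheres)
        object.__setattr__(self, "spheres", spheres)
        for i, a in enumerate(spheres):
            for b in spheres[i + 1 :]:
                dist = math.dist(a.center, b.center)
                if dist < a.radius + b.radius:
                    raise ValueError(
                        f"spheres at {a.center} and {b.center} overlap"
                    )

    @classmethod
    def uniform_cylinder(
        cls,
        length: float = 211.0,
        diameter: float = 195.0,
        concentration: float | None = None,
        total_activity: float | None = None,
    ) -> "PhantomSpec":
        """The calibration cylinder (default 195 mm x 211 mm, 6.3 L).

        Provide either the activity concentration (MBq/mL) or the total
        activity (MBq, default 800 MBq nominal fill).
        """
        if concentration is None:
            if total_activity is None:
                total_activity = 800.0
            concentration = total_activity / (cylinder_volume(diameter, length) * 1000.0)
        return cls(
            kind="cylinder",
            cylinder_length=length,
            cylinder_diameter=diameter,
            cylinder_concentration=concentration,
        )

    @classmethod
    def nema_iq(
        cls,
        sphere_diameters: tuple[float, ...] = NEMA_SPHERE_DIAMETERS,
        sphere_concentration: float = 4.0,
        background_concentration: float = 0.0,
        body_diameter: float = 240.0,
        body_length: float = 180.0,
    ) -> "PhantomSpec":
        """NEMA IQ phantom with six hot spheres (default 4 MBq/mL) in a
        cold background, body approximated by a cylinder envelope."""
        return cls(
            kind="nema_iq",
            cylinder_length=body_length,
            cylinder_diameter=body_diameter,
            spheres=tuple(
                default_nema_spheres(sphere_diameters, sphere_concentration)
            ),
            background_concentration=background_concentration,
        )

    @property
    def cylinder_volume_L(self) -> float:
        return cylinder_volume(self.cylinder_diameter, self.cylinder_length)

    @property
    def total_activity_MBq(self) -> float:
        """Analytic total activity of all compartments."""
        if self.kind == "cylinder":
            return self.cylinder_concentration * self.cylinder_volume_L * 1000.0
        act = self.background_concentration * (
            self.cylinder_volume_L * 1000.0
            - sum(s.volume_mL for s in self.spheres)
        )
        act += sum(s.activity_concentration * s.volume_mL for s in self.spheres)
        return act


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid: shape, spacing (mm/axis) and world coordinate of the
    grid centre (phantom centre sits at the grid centre by default)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")

    @classmethod
    def isotropic(cls, extent_mm: tuple[float, float, float], spacing: float,
                  origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "GridSpec":
        shape = tuple(int(math.ceil(e / spacing)) for e in extent_mm)
        return cls(shape=shape, spacing=(spacing,) * 3, origin=origin)

    @classmethod
    def for_phantom(cls, spec: PhantomSpec, spacing: float,
                    margin: float = 30.0) -> "GridSpec":
        """Grid containing the phantom plus an isotropic margin (mm)."""
        extent = (
            spec.cylinder_diameter + 2 * margin,
            spec.cylinder_diameter + 2 * margin,
            spec.cylinder_length + 2 * margin,
        )
        return cls.isotropic(extent, spacing)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of voxel centres along each axis."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * s + o
            for n, s, o in zip(self.shape, self.spacing, self.origin)
        )

    @property
    def voxel_volume_mL(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def extent(self) -> list[tuple[float, float]]:
        """(min, max) world coordinate covered by the grid per axis."""
        return [
            (o - n * s / 2.0, o + n * s / 2.0)
            for n, s, o in zip(self.shape, self.spacing, self.origin)
        ]


def _phantom_bounds(spec: PhantomSpec) -> list[tuple[float, float]]:
    r = spec.cylinder_diameter / 2.0
    h = spec.cylinder_length / 2.0
    return [(-r, r), (-r, r), (-h, h)]


def voxelize(spec: PhantomSpec, grid: GridSpec) -> np.ndarray:
    """Rasterize a phantom onto a grid, returning the ground-truth
    activity-concentration map in MBq/mL.

    Each voxel takes the concentration of the compartment containing its
    centre; the integrated activity converges to the analytic value as
    the spacing decreases.  Raises if the grid clips the phantom.
    """
    for (lo, hi), (glo, ghi) in zip(_phantom_bounds(spec), grid.extent()):
        if lo < glo or hi > ghi:
            raise ValueError("grid does not fully contain the phantom")
    ax, ay, az = grid.axes()
    X = ax[:, None, None]
    Y = ay[None, :, None]
    Z = az[None, None, :]
    r2 = X**2 + Y**2
    body = (r2 <= (spec.cylinder_diameter / 2.0) ** 2) & (
        np.abs(Z) <= spec.cylinder_length / 2.0
    )
    if spec.kind == "cylinder":
        return np.where(body, spec.cylinder_concentration, 0.0)
    values = np.where(body, spec.background_concentration, 0.0)
    for s in spec.spheres:
        d2 = (X - s.center[0]) ** 2 + (Y - s.center[1]) ** 2 + (Z - s.center[2]) ** 2
        values = np.where(d2 <= s.radius**2, s.activity_concentration, values)
    return values
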