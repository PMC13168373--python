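"""In-memory image container and NIfTI + JSON-sidecar I/O.

A :class:`VoxelImage` is a 3-D voxel grid with explicit physical
metadata: voxel spacing in mm, value units (``counts``, ``Bq/mL`` or
``MBq/mL``), the acquisition duration (mandatory for counts images,
since counts are only quantifiable per unit time) and an optional
resolution-recovery projection scale recorded by some reconstructions.
Units are always carried explicitly in the sidecar — they are never
inferred from value magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantoms import GridSpec

__all__ = ["VoxelImage", "read_image", "write_image", "UNITS"]

UNITS = ("counts", "Bq/mL", "MBq/mL")


@dataclass
class VoxelImage:
    """3-D image with physical metadata.

    Parameters
    ----------
    values : ndarray
        Voxel values, shape (nx, ny, nz).
    spacing : tuple of float
        Voxel size in mm per axis.
    units : str
        One of ``counts``, ``Bq/mL``, ``MBq/mL``.
    duration : float, optional
        Acquisition duration in seconds; required when units are counts.
    rr_scale : float
        Projection scale applied by the reconstruction (e.g. 4 for
        resolution-recovery conventions that multiply counts); purely
        declarative sidecar metadata.
    origin : tuple of float
        World coordinate (mm) of the grid centre.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    units: str
    duration: float | None = None
    rr_scale: float = 1.0
    system_id: str = ""
    scenario: str = ""
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if self.units == "counts":
            if self.duration is None or self.duration <= 0:
                raise ValueError("counts images require a positive duration")
        if self.rr_scale <= 0:
            raise ValueError("rr_scale must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(shape=self.values.shape, spacing=self.spacing,
                        origin=self.origin)

    @property
    def voxel_volume_mL(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def with_values(self, values: np.ndarray) -> "VoxelImage":
        return replace(self, values=values)


def write_image(image: VoxelImage, path: str | Path,
                sidecar_path: str | Path | None = None) -> None:
    """Write a NIfTI volume plus a JSON sidecar with the metadata."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    affine = np.diag(list(image.spacing) + [1.0])
    # place the grid centre at the stored world origin
    for i in range(3):
        affine[i, 3] = image.origin[i] - (image.values.shape[i] - 1) / 2.0 * image.spacing[i]
    nib.save(nib.Nifti1Image(image.values, affine), str(path))
    meta = {
        "units": image.units,
        "duration_s": image.duration,
        "rr_scale": image.rr_scale,
        "system_id": image.system_id,
        "scenario": image.scenario,
        "origin_mm": list(image.origin),
    }
    sidecar_path.write_text(json.dumps(meta, indent=2))


def read_image(path: str | Path,
               sidecar_path: str | Path | None = None) -> VoxelImage:
    """Read a NIfTI volume and its JSON sidecar; validates the metadata
    (counts images must declare a duration; units must be known)."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta = json.loads(Path(sidecar_path).read_text())
    return VoxelImage(
        values=values,
        spacing=spacing,
        units=meta["units"],
        duration=meta.get("duration_s"),
        rr_scale=float(meta.get("rr_scale", 1.0)),
        system_id=meta.get("system_id", ""),
        scenario=meta.get("scenario", ""),
        origin=tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))),
    )
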