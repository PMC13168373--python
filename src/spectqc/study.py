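"""End-to-end multicenter-style study orchestration.

A study manifest defines a grid of synthetic "systems" (each one a
reconstruction model emulating one scanner family's behaviour) crossed
with protocol scenarios (non-standardized: per-system clinical
reconstruction parameters; semi/fully standardized: common
reconstruction parameters per family).  For every (system, scenario)
cell the study simulates the calibration cylinder and the NEMA phantom,
derives the ICF (counts systems) or CF (Bq/mL systems) from the
cylinder, computes the sphere recovery curve and the Gibbs-artifact
strength of the largest sphere, and aggregates recovery bands and
spreads per system family.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import compute_cf, compute_icf, place_cylinder_voi
from .gibbs import analyze_gibbs
from .phantoms import PhantomSpec
from .recovery import (RecoveryCurve, compute_recovery_curve, locate_spheres,
                       recovery_band, rc_spread, segment_spheres)
from .simulate import ReconstructionModel, simulate_phantom

log = logging.getLogger(__name__)

__all__ = ["SystemSpec", "StudyManifest", "StudyResult", "run_study",
           "render_reports", "default_manifest"]

SCENARIOS = ("non_standardized", "semi_standardized", "fully_standardized")


@dataclass(frozen=True)
class SystemSpec:
    """One synthetic scanner: its family and the reconstruction-model
    parameters used per scenario (standardized scenarios share the
    family's standard parameters)."""

    name: str
    family: str
    icf_true: float = 20.0
    units_out: str = "counts"
    quant_bias: float = 1.0
    rr_scale: float = 1.0
    clinical_fwhm: float = 12.0
    clinical_beta: float = 0.0
    standard_fwhm: float = 12.0
    standard_beta: float = 0.0
    ringing_alpha: float = 2.0

    def model(self, scenario: str, phantom_kind: str, seed: int,
              count_targets: dict[str, float]) -> ReconstructionModel:
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}")
        clinical = scenario == "non_standardized"
        return ReconstructionModel(
            psf_fwhm=self.clinical_fwhm if clinical else self.standard_fwhm,
            ringing_beta=self.clinical_beta if clinical else self.standard_beta,
            ringing_alpha=self.ringing_alpha,
            icf_true=self.icf_true,
            quant_bias=self.quant_bias,
            count_target=count_targets[phantom_kind],
            noise="poisson",
            seed=seed,
            units_out=self.units_out,
            rr_scale=self.rr_scale if self.units_out == "counts" else 1.0,
            system_id=self.name,
            scenario=scenario,
        )


def default_manifest(seed: int = 0, spacing: float = 4.0,
                     scenarios=SCENARIOS) -> "StudyManifest":
    """Seven synthetic systems spanning four scanner families:
    high-sensitivity cameras with strong edge ringing (Symbia-like),
    low-sensitivity cameras without ringing but with a x4 projection
    scale (Discovery-like), CZT ring systems (Starguide-like) and
    Bq/mL-native CZT systems with a quantification bias (Veriton-like)."""
    systems = (
        SystemSpec("sym1", "symbia", icf_true=20.0, clinical_fwhm=10.0,
                   clinical_beta=0.45, standard_fwhm=11.0, standard_beta=0.35),
        SystemSpec("sym2", "symbia", icf_true=20.0, clinical_fwhm=13.0,
                   clinical_beta=0.15, standard_fwhm=11.0, standard_beta=0.35),
        SystemSpec("sym3", "symbia", icf_true=25.0, clinical_fwhm=11.0,
                   clinical_beta=0.3, standard_fwhm=11.0, standard_beta=0.35),
        SystemSpec("dis1", "discovery", icf_true=12.0, rr_scale=4.0,
                   clinical_fwhm=16.0, clinical_beta=0.0,
                   standard_fwhm=14.0, standard_beta=0.0),
        SystemSpec("dis2", "discovery", icf_true=12.0, rr_scale=4.0,
                   clinical_fwhm=15.0, clinical_beta=0.0,
                   standard_fwhm=14.0, standard_beta=0.0),
        SystemSpec("star1", "starguide", icf_true=7.0, clinical_fwhm=14.0,
                   clinical_beta=0.1, standard_fwhm=13.0, standard_beta=0.15),
        SystemSpec("ver1", "veriton", icf_true=15.0, units_out="Bq/mL",
                   quant_bias=1.1, clinical_fwhm=12.0, clinical_beta=0.4,
                   standard_fwhm=12.0, standard_beta=0.3),
    )
    return StudyManifest(systems=systems, scenarios=tuple(scenarios),
                         seed=seed, spacing=spacing)


@dataclass(frozen=True)
class StudyManifest:
    systems: tuple[SystemSpec, ...]
    scenarios: tuple[str, ...] = SCENARIOS
    seed: int = 0
    spacing: float = 4.0  # mm voxels
    count_targets: dict = field(
        default_factory=lambda: {"cylinder": 7e6, "nema_iq": 3e6})

    def __post_init__(self) -> None:
        keys = [(s.name, sc) for s in self.systems for sc in self.scenarios]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (system, scenario) keys in manifest")


@dataclass
class StudyResult:
    calibration: pd.DataFrame  # system, scenario, kind (icf|cf), value, voi_sd
    recovery: pd.DataFrame     # system, scenario, family, diameter_mm, rc
    gibbs: pd.DataFrame        # system, scenario, ga
    bands: pd.DataFrame        # family, scenario, diameter_mm, mean, min, max
    spreads: pd.DataFrame      # scenario, diameter_mm, spread_pp
    curves: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)


def _analyze_cell(system: SystemSpec, scenario: str, manifest: StudyManifest,
                  cylinder: PhantomSpec, nema: PhantomSpec, seed: int):
    cyl_model = system.model(scenario, "cylinder", seed, manifest.count_targets)
    nem_model = system.model(scenario, "nema_iq", seed + 1, manifest.count_targets)
    cyl_img = simulate_phantom(cylinder, cyl_model, spacing=manifest.spacing)
    nem_img = simulate_phantom(nema, nem_model, spacing=manifest.spacing)

    ref_conc_cyl = cylinder.cylinder_concentration
    voi = place_cylinder_voi(cyl_img, cylinder)
    if system.units_out == "counts":
        calib = compute_icf(cyl_img, voi, ref_conc_cyl)
        cal_kind, cal_value, cal_sd = "icf", calib.icf, calib.voi_sd
    else:
        calib = compute_cf(cyl_img, voi, ref_conc_cyl)
        cal_kind, cal_value, cal_sd = "cf", calib.cf, calib.voi_sd

    ref_conc = nema.spheres[0].activity_concentration
    fwhm = (system.clinical_fwhm if scenario == "non_standardized"
            else system.standard_fwhm)
    locs = locate_spheres(nem_img, nema, psf_fwhm=fwhm)
    centers = [l.center for l in locs]
    diameters = [l.diameter for l in locs]
    masks = segment_spheres(centers, diameters, nem_img.grid)
    curve = compute_recovery_curve(nem_img, masks, diameters, calib, ref_conc)

    largest = int(np.argmax(diameters))
    ga = analyze_gibbs(nem_img, centers[largest], diameters[largest],
                       ref_conc, calib,
                       background_concentration=nema.background_concentration)
    return cal_kind, cal_value, cal_sd, curve, ga


def run_study(manifest: StudyManifest,
              cylinder: PhantomSpec | None = None,
              nema: PhantomSpec | None = None) -> StudyResult:
    """Run every (system, scenario) cell; partial failures are recorded
    and the run continues.  Deterministic for a fixed manifest seed."""
    cylinder = cylinder or PhantomSpec.uniform_cylinder()
    nema = nema or PhantomSpec.nema_iq()
    cal_rows, rc_rows, ga_rows = [], [], []
    curves: dict[tuple[str, str], RecoveryCurve] = {}
    failures = []
    for i, system in enumerate(manifest.systems):
        for j, scenario in enumerate(manifest.scenarios):
            seed = manifest.seed + 1000 * i + 10 * j
            try:
                kind, value, sd, curve, ga = _analyze_cell(
                    system, scenario, manifest, cylinder, nema, seed)
            except Exception as exc:  # keep going, report per cell
                log.warning("cell (%s, %s) failed: %s", system.name, scenario, exc)
                failures.append({"system": system.name, "scenario": scenario,
                                 "error": str(exc)})
                continue
            cal_rows.append({"system": system.name, "scenario": scenario,
                             "family": system.family, "kind": kind,
                             "value": value, "voi_sd": sd, "seed": seed})
            for m in curve.measurements:
                rc_rows.append({"system": system.name, "scenario": scenario,
                                "family": system.family,
                                "diameter_mm": m.diameter, "rc": m.rc})
            ga_rows.append({"system": system.name, "scenario": scenario,
                            "family": system.family, "ga": ga.ga})
            curves[(system.name, scenario)] = curve

    band_rows, spread_rows = [], []
    for scenario in manifest.scenarios:
        sc_curves = [curves[k] for k in curves if k[1] == scenario]
        if len(sc_curves) >= 2:
            for d in sc_curves[0].diameters:
                spread_rows.append({"scenario": scenario, "diameter_mm": d,
                                    "spread_pp": rc_spread(sc_curves, d)})
        families = {s.family for s in manifest.systems}
        for fam in sorted(families):
            fam_curves = [curves[(s.name, scenario)] for s in manifest.systems
                          if s.family == fam and (s.name, scenario) in curves]
            if not fam_curves:
                continue
            band = recovery_band(fam_curves)
            band.insert(0, "scenario", scenario)
            band.insert(0, "family", fam)
            band_rows.append(band)

    return StudyResult(
        calibration=pd.DataFrame(cal_rows),
        recovery=pd.DataFrame(rc_rows),
        gibbs=pd.DataFrame(ga_rows, columns=["system", "scenario", "family", "ga"]),
        bands=(pd.concat(band_rows, ignore_index=True) if band_rows
               else pd.DataFrame(columns=["family", "scenario", "diameter_mm",
                                          "mean", "min", "max"])),
        spreads=pd.DataFrame(spread_rows,
                             columns=["scenario", "diameter_mm", "spread_pp"]),
        curves=curves,
        failures=failures,
    )


def render_reports(result: StudyResult, outdir: str | Path,
                   manifest: StudyManifest | None = None,
                   plots: bool = True) -> dict:
    """Write result tables as CSV (plus plots) under a run directory
    with a machine-readable index.json recording provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name in ("calibration", "recovery", "gibbs", "bands", "spreads"):
        df: pd.DataFrame = getattr(result, name)
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        files[name] = path.name
    if plots and not result.bands.empty:
        files.update(_plot_bands(result.bands, outdir))
    index = {
        "version": __version__,
        "files": files,
        "failures": result.failures,
    }
    if manifest is not None:
        index["seed"] = manifest.seed
        index["spacing_mm"] = manifest.spacing
        index["systems"] = [dataclasses.asdict(s) for s in manifest.systems]
        index["scenarios"] = list(manifest.scenarios)
    (outdir / "index.json").write_text(json.dumps(index, indent=2))
    return index


def _plot_bands(bands: pd.DataFrame, outdir: Path) -> dict:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = {}
    for scenario, sc in bands.groupby("scenario"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for fam, grp in sc.groupby("family"):
            grp = grp.sort_values("diameter_mm")
            line, = ax.plot(grp["diameter_mm"], grp["mean"], "--", label=fam)
            ax.plot(grp["diameter_mm"], grp["min"], "-", color=line.get_color(),
                    alpha=0.6)
            ax.plot(grp["diameter_mm"], grp["max"], "-", color=line.get_color(),
                    alpha=0.6)
        ax.set_xlabel("sphere diameter (mm)")
        ax.set_ylabel("recovery coefficient")
        ax.set_title(f"recovery bands — {scenario}")
        ax.legend()
        fig.tight_layout()
        name = f"bands_{scenario}.png"
        fig.savefig(outdir / name, dpi=120)
        plt.close(fig)
        files[f"plot_{scenario}"] = name
    return files
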