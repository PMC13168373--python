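"""Run-configuration loading with defaults and schema validation."""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .phantoms import NEMA_SPHERE_DIAMETERS, PhantomSpec
from .simulate import ReconstructionModel

__all__ = ["DEFAULT_CONFIG", "load_run_config", "phantom_from_config",
           "model_from_config"]

DEFAULT_CONFIG = {
    "phantom": {
        "cylinder": {
            "length_mm": 211.0,
            "diameter_mm": 195.0,
            "total_activity_MBq": 800.0,
        },
        "nema": {
            "sphere_diameters_mm": list(NEMA_SPHERE_DIAMETERS),
            "sphere_concentration_MBq_per_mL": 4.0,
            "background_concentration_MBq_per_mL": 0.0,
            "body_diameter_mm": 240.0,
            "body_length_mm": 180.0,
        },
    },
    "voi": {"diameter_mm": 120.0, "length_mm": 150.0},
    "grid": {"spacing_mm": 4.0, "margin_mm": 30.0},
    "simulate": {
        "psf_fwhm_mm": 12.0,
        "ringing_beta": 0.0,
        "ringing_alpha": 2.0,
        "icf_true_cps_per_MBq": 20.0,
        "quant_bias": 1.0,
        "count_target_cylinder": 7e6,
        "count_target_nema": 3e6,
        "noise": "poisson",
        "units_out": "counts",
        "rr_scale": 1.0,
        "seed": 0,
    },
    "gibbs": {"search_fraction": 0.9, "sphere_diameter_mm": 60.0},
    "half_life_days": 6.6443,
}


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown configuration key {where!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"{where!r} must be a mapping")
            out[key] = _merge(defaults[key], val, where)
        else:
            out[key] = val
    return out


def _validate(cfg: dict) -> None:
    sim = cfg["simulate"]
    if sim["psf_fwhm_mm"] < 0:
        raise ValueError("simulate.psf_fwhm_mm must be >= 0")
    if sim["ringing_beta"] < 0:
        raise ValueError("simulate.ringing_beta must be >= 0")
    if sim["ringing_alpha"] <= 1:
        raise ValueError("simulate.ringing_alpha must be > 1")
    for key in ("icf_true_cps_per_MBq", "count_target_cylinder",
                "count_target_nema", "quant_bias", "rr_scale"):
        if sim[key] <= 0:
            raise ValueError(f"simulate.{key} must be positive")
    for key in ("diameter_mm", "length_mm"):
        if cfg["voi"][key] <= 0:
            raise ValueError(f"voi.{key} must be positive")
    if cfg["grid"]["spacing_mm"] <= 0:
        raise ValueError("grid.spacing_mm must be positive")
    if cfg["half_life_days"] <= 0:
        raise ValueError("half_life_days must be positive")


def load_run_config(path: str | Path | None = None) -> dict:
    """Load a YAML/JSON run configuration, apply defaults, reject
    unknown keys and validate ranges.  ``None`` gives the full default
    set."""
    overrides: dict = {}
    if path is not None:
        text = Path(path).read_text()
        overrides = (json.loads(text) if str(path).endswith(".json")
                     else yaml.safe_load(text)) or {}
    cfg = _merge(DEFAULT_CONFIG, overrides)
    _validate(cfg)
    return cfg


def phantom_from_config(cfg: dict, kind: str) -> PhantomSpec:
    if kind == "cylinder":
        c = cfg["phantom"]["cylinder"]
        return PhantomSpec.uniform_cylinder(
            length=c["length_mm"], diameter=c["diameter_mm"],
            total_activity=c["total_activity_MBq"])
    if kind in ("nema", "nema_iq"):
        n = cfg["phantom"]["nema"]
        return PhantomSpec.nema_iq(
            sphere_diameters=tuple(n["sphere_diameters_mm"]),
            sphere_concentration=n["sphere_concentration_MBq_per_mL"],
            background_concentration=n["background_concentration_MBq_per_mL"],
            body_diameter=n["body_diameter_mm"],
            body_length=n["body_length_mm"])
    raise ValueError(f"unknown phantom kind {kind!r}")


def model_from_config(cfg: dict, phantom_kind: str, **overrides) -> ReconstructionModel:
    sim = cfg["simulate"]
    target = (sim["count_target_cylinder"] if phantom_kind == "cylinder"
              else sim["count_target_nema"])
    kwargs = dict(
        psf_fwhm=sim["psf_fwhm_mm"],
        ringing_beta=sim["ringing_beta"],
        ringing_alpha=sim["ringing_alpha"],
        icf_true=sim["icf_true_cps_per_MBq"],
        quant_bias=sim["quant_bias"],
        count_target=target,
        noise=sim["noise"],
        units_out=sim["units_out"],
        rr_scale=sim["rr_scale"],
        seed=sim["seed"],
    )
    kwargs.update(overrides)
    return ReconstructionModel(**kwargs)
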