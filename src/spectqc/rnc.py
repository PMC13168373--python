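"""Radionuclide-calibrator (RNC) metrology.

A well-type ionization chamber reads an activity through an
isotope-specific "dial setting".  Sessions of repeated readings of a
vial (repositioned between readings, spread over hours) are background
corrected, decay corrected to a common reference time and averaged; the
mean deviation from a traceable reference activity drives a corrected
dial setting.  A geometry correction factor compares the chamber's
relative response to two vial geometries.  Uncertainty budgets follow
the GUM quadrature convention with a coverage factor k.

Chamber dial-response conventions
---------------------------------
``vik202``   reading locally proportional to the dial setting
``crc55tr``  reading locally proportional to the inverse dial setting
``generic``  user-supplied fractional sensitivity per dial unit

These response models are pluggable because vendor manuals differ; the
two named models capture the direction of real factory-to-corrected
dial steps for the corresponding chambers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LU177_HALF_LIFE_DAYS",
    "RNCReading",
    "RNCSession",
    "SessionSummary",
    "UncertaintyComponent",
    "UncertaintyBudget",
    "decay_correct",
    "summarize_session",
    "corrected_dial",
    "dial_response_ratio",
    "geometry_correction_factor",
    "combine_uncertainty",
    "read_session_csv",
    "write_session_csv",
]

#: Physical half-life of Lu-177 in days.
LU177_HALF_LIFE_DAYS = 6.6443

CHAMBER_MODELS = ("vik202", "crc55tr", "generic")


@dataclass(frozen=True)
class RNCReading:
    timestamp: datetime
    raw_reading: float  # MBq
    background: float = 0.0  # MBq

    def __post_init__(self) -> None:
        if self.raw_reading < 0:
            raise ValueError("raw reading must be >= 0")


@dataclass
class RNCSession:
    readings: list[RNCReading]
    ref_time: datetime
    protocol: str = "factory"  # factory | clinical
    chamber_model: str = "generic"
    dial_setting: int = 0
    vial_geometry: str = ""

    def __post_init__(self) -> None:
        if not self.readings:
            raise ValueError("session needs at least one reading")
        if self.protocol not in ("factory", "clinical"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.chamber_model not in CHAMBER_MODELS:
            raise ValueError(f"unknown chamber model {self.chamber_model!r}")


def decay_correct(activity: float, t: datetime, t_ref: datetime,
                  half_life_days: float = LU177_HALF_LIFE_DAYS) -> float:
    """Activity at the reference time given a measurement at time t.

    For t after t_ref the source has decayed, so the reference-time
    activity is larger: A_ref = A(t) * 2**((t - t_ref)/T_half).
    """
    if half_life_days <= 0:
        raise ValueError("half-life must be positive")
    dt_days = (t - t_ref) / timedelta(days=1)
    return activity * 2.0 ** (dt_days / half_life_days)


@dataclass(frozen=True)
class SessionSummary:
    deviation_pct: float  # mean corrected reading vs reference, %
    sd_pct: float | None  # relative sample SD of corrected readings, %
    n: int
    mean_corrected_MBq: float


def summarize_session(session: RNCSession, ref_activity_at_ref_time: float,
                      half_life_days: float = LU177_HALF_LIFE_DAYS) -> SessionSummary:
    """Background-correct each reading, decay-correct it to the session
    reference time, average, and express the deviation from the
    traceable reference activity in percent.

    The sample SD is undefined (None) for single-reading sessions.
    """
    if ref_activity_at_ref_time <= 0:
        raise ValueError("reference activity must be positive")
    corrected = np.array([
        decay_correct(r.raw_reading - r.background, r.timestamp,
                      session.ref_time, half_life_days)
        for r in session.readings
    ])
    mean = float(corrected.mean())
    sd_pct = None
    if corrected.size >= 2 and mean != 0:
        sd_pct = float(corrected.std(ddof=1) / abs(mean) * 100.0)
    deviation = mean / ref_activity_at_ref_time - 1.0
    return SessionSummary(deviation_pct=deviation * 100.0, sd_pct=sd_pct,
                          n=corrected.size, mean_corrected_MBq=mean)


def dial_response_ratio(chamber_model: str, dial_old: int, dial_new: int,
                        sensitivity: float | None = None) -> float:
    """Multiplicative change in chamber response when the dial moves
    from dial_old to dial_new under the given response model."""
    if chamber_model == "vik202":
        return dial_new / dial_old
    if chamber_model == "crc55tr":
        return dial_old / dial_new
    if chamber_model == "generic":
        if sensitivity is None:
            raise ValueError("generic chamber model requires a sensitivity")
        return 1.0 + sensitivity * (dial_new - dial_old)
    raise ValueError(f"unknown chamber model {chamber_model!r}")


def corrected_dial(dial: int, deviation: float, chamber_model: str,
                   sensitivity: float | None = None) -> int:
    """Dial setting that nulls an observed fractional deviation.

    ``deviation`` is the fractional reading error at the current dial
    (e.g. +0.0093 for a +0.93% overestimate).
    """
    if abs(deviation) >= 0.5:
        raise ValueError("deviation out of the supported +/-50% range")
    if chamber_model == "vik202":
        return round(dial / (1.0 + deviation))
    if chamber_model == "crc55tr":
        return round(dial * (1.0 + deviation))
    if chamber_model == "generic":
        if sensitivity is None:
            raise ValueError("generic chamber model requires a sensitivity")
        return round(dial + (1.0 / (1.0 + deviation) - 1.0) / sensitivity)
    raise ValueError(f"unknown chamber model {chamber_model!r}")


def geometry_correction_factor(session_ref: RNCSession, session_clin: RNCSession,
                               true_ref: float, true_clin: float,
                               half_life_days: float = LU177_HALF_LIFE_DAYS) -> float:
    """Relative chamber response to the clinical vial geometry versus
    the reference geometry: (response_clin/true_clin) / (response_ref/true_ref).

    A factor > 1 means the clinical geometry reads relatively high; a
    clinical reading is corrected by dividing by this factor.  Both
    sessions must come from the same chamber and dial setting.
    """
    if true_ref <= 0 or true_clin <= 0:
        raise ValueError("true activities must be positive")
    if (session_ref.chamber_model != session_clin.chamber_model
            or session_ref.dial_setting != session_clin.dial_setting):
        raise ValueError("sessions must share chamber model and dial setting")
    s_ref = summarize_session(session_ref, true_ref, half_life_days)
    s_clin = summarize_session(session_clin, true_clin, half_life_days)
    return (1.0 + s_clin.deviation_pct / 100.0) / (1.0 + s_ref.deviation_pct / 100.0)


# --- uncertainty budgets -------------------------------------------------

DISTRIBUTIONS = ("normal_k1", "normal_k2", "rectangular_halfwidth")
_STANDARDIZE = {"normal_k1": 1.0, "normal_k2": 2.0,
                "rectangular_halfwidth": np.sqrt(3.0)}


@dataclass(frozen=True)
class UncertaintyComponent:
    label: str
    magnitude: float  # percent
    distribution: str = "normal_k1"

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}")

    @property
    def standard(self) -> float:
        """Standard uncertainty (%, k=1 equivalent)."""
        return self.magnitude / _STANDARDIZE[self.distribution]


@dataclass(frozen=True)
class UncertaintyBudget:
    components: tuple[UncertaintyComponent, ...]
    k: float = 2.0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("budget needs at least one component")
        object.__setattr__(self, "components", tuple(self.components))


def combine_uncertainty(budget: UncertaintyBudget) -> float:
    """Expanded uncertainty in percent: each component converted to a
    standard uncertainty, combined in quadrature, multiplied by k."""
    combined = np.sqrt(sum(c.standard**2 for c in budget.components))
    return float(budget.k * combined)


# --- CSV I/O -------------------------------------------------------------

def write_session_csv(session: RNCSession, path: str | Path) -> None:
    df = pd.DataFrame({
        "timestamp": [r.timestamp.isoformat() for r in session.readings],
        "raw_MBq": [r.raw_reading for r in session.readings],
        "background_MBq": [r.background for r in session.readings],
        "protocol": session.protocol,
        "chamber": session.chamber_model,
        "dial": session.dial_setting,
        "vial_id": session.vial_geometry,
        "ref_time": session.ref_time.isoformat(),
    })
    df.to_csv(path, index=False)


def read_session_csv(path: str | Path) -> RNCSession:
    df = pd.read_csv(path)
    readings = [
        RNCReading(timestamp=datetime.fromisoformat(row.timestamp),
                   raw_reading=row.raw_MBq, background=row.background_MBq)
        for row in df.itertuples()
    ]
    first = df.iloc[0]
    return RNCSession(
        readings=readings,
        ref_time=datetime.fromisoformat(str(first["ref_time"])),
        protocol=str(first["protocol"]),
        chamber_model=str(first["chamber"]),
        dial_setting=int(first["dial"]),
        vial_geometry=str(first["vial_id"]),
    )
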