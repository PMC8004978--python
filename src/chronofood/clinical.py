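"""Clinical derivations and metabolic-syndrome component classification.

Component criteria follow the IDF consensus definition with sex-specific
cut-offs: central obesity (BMI >= 30 kg/m2 or waist circumference >= 80 cm in
women / >= 94 cm in men), hypertension (SBP >= 130 and/or DBP >= 85 mmHg),
impaired fasting glucose (>= 5.6 mmol/L), high triglycerides (>= 1.7 mmol/L)
and low HDL cholesterol (< 1.29 mmol/L women / < 1.03 mmol/L men).  The full
metabolic-syndrome diagnosis requires central obesity plus at least two other
components.  All concentrations are SI (mmol/L); a mg/dL converter is
provided but never applied implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "ClinicalMeasurements",
    "MsProfile",
    "bmi",
    "classify_ms_components",
    "ms_table",
    "mean_last_two",
    "mgdl_to_mmol",
]

# conversion factors mg/dL -> mmol/L
_MGDL_FACTORS = {"glucose": 1 / 18.016, "triglycerides": 1 / 88.57, "hdl": 1 / 38.67}

THRESHOLDS = {
    "bmi_obesity": 30.0,        # kg/m2
    "wc_female": 80.0,          # cm
    "wc_male": 94.0,            # cm
    "sbp": 130.0,               # mmHg
    "dbp": 85.0,                # mmHg
    "glucose": 5.6,             # mmol/L
    "triglycerides": 1.7,       # mmol/L
    "hdl_female": 1.29,         # mmol/L (low if below)
    "hdl_male": 1.03,           # mmol/L (low if below)
}

COMPONENTS = (
    "central_obesity",
    "hypertension",
    "impaired_fasting_glucose",
    "high_triglycerides",
    "low_hdl",
)


@dataclass(frozen=True)
class ClinicalMeasurements:
    """One participant's clinical measurement set (SI units).

    Any field may be NaN; the classifier then reports that component as
    missing rather than guessing.
    """

    sex: str
    age: float = math.nan
    weight: float = math.nan       # kg
    height: float = math.nan       # m
    waist: float = math.nan        # cm
    sbp: float = math.nan          # mmHg
    dbp: float = math.nan          # mmHg
    glucose: float = math.nan      # mmol/L, fasting
    triglycerides: float = math.nan  # mmol/L, fasting
    hdl: float = math.nan          # mmol/L, fasting
    hba1c: float = math.nan        # %

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not math.isnan(self.height) and not 1.0 < self.height < 2.5:
            raise ValueError(f"height {self.height} m implausible; expected metres")
        for name in ("weight", "waist", "sbp", "dbp", "glucose", "triglycerides", "hdl"):
            v = getattr(self, name)
            if not math.isnan(v) and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class MsProfile:
    """Per-component flags, their count, and the full IDF diagnosis.

    ``complete`` is False when any component could not be evaluated; the
    count then covers the evaluable components only.
    """

    central_obesity: bool | None
    hypertension: bool | None
    impaired_fasting_glucose: bool | None
    high_triglycerides: bool | None
    low_hdl: bool | None
    component_count: int
    ms_idf: bool
    complete: bool


def bmi(weight: float, height: float) -> float:
    """Body-mass index: weight (kg) divided by height (m) squared."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return weight / height**2


def mean_last_two(readings: Sequence[float]) -> float:
    """Blood-pressure preprocessing: mean of the last two of three readings."""
    if len(readings) != 3:
        raise ValueError(f"expected exactly 3 readings, got {len(readings)}")
    return (readings[1] + readings[2]) / 2.0


def mgdl_to_mmol(value: float, analyte: str) -> float:
    """Convert glucose / triglycerides / HDL from mg/dL to mmol/L."""
    try:
        return value * _MGDL_FACTORS[analyte]
    except KeyError:
        raise ValueError(f"unknown analyte {analyte!r}") from None


def _flag(value: float, threshold: float, low_is_bad: bool = False) -> bool | None:
    if math.isnan(value):
        return None
    return value < threshold if low_is_bad else value >= threshold


def classify_ms_components(m: ClinicalMeasurements) -> MsProfile:
    """Classify the five metabolic-syndrome components for one participant.

    Missing measurements yield a None flag for that component; the component
    count then runs over the evaluable flags and ``complete`` marks whether
    every component could be assessed.
    """
    female = m.sex == "female"

    bmi_flag = None
    if not (math.isnan(m.weight) or math.isnan(m.height)):
        bmi_flag = bmi(m.weight, m.height) >= THRESHOLDS["bmi_obesity"]
    wc_flag = _flag(m.waist, THRESHOLDS["wc_female" if female else "wc_male"])
    if bmi_flag is None and wc_flag is None:
        central = None
    else:
        central = bool(bmi_flag) or bool(wc_flag)

    sbp_flag = _flag(m.sbp, THRESHOLDS["sbp"])
    dbp_flag = _flag(m.dbp, THRESHOLDS["dbp"])
    if sbp_flag is None and dbp_flag is None:
        hypertension = None
    else:
        hypertension = bool(sbp_flag) or bool(dbp_flag)

    ifg = _flag(m.glucose, THRESHOLDS["glucose"])
    tg = _flag(m.triglycerides, THRESHOLDS["triglycerides"])
    hdl = _flag(m.hdl, THRESHOLDS["hdl_female" if female else "hdl_male"], low_is_bad=True)

    flags = (central, hypertension, ifg, tg, hdl)
    count = sum(bool(f) for f in flags if f is not None)
    complete = all(f is not None for f in flags)
    others = sum(bool(f) for f in flags[1:] if f is not None)
    ms = bool(central) and others >= 2
    return MsProfile(
        central_obesity=central,
        hypertension=hypertension,
        impaired_fasting_glucose=ifg,
        high_triglycerides=tg,
        low_hdl=hdl,
        component_count=count,
        ms_idf=ms,
        complete=complete,
    )


def ms_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification over a participant table.

    Expects columns matching :class:`ClinicalMeasurements` field names plus
    ``participant_id``; returns one row per participant with component flags,
    count and diagnosis.
    """
    rows = []
    field_names = (
        "sex", "age", "weight", "height", "waist", "sbp", "dbp",
        "glucose", "triglycerides", "hdl", "hba1c",
    )
    for _, rec in measurements.iterrows():
        kwargs = {}
        for f in field_names:
            if f in rec.index and (f == "sex" or pd.notna(rec[f])):
                kwargs[f] = rec[f]
        profile = classify_ms_components(ClinicalMeasurements(**kwargs))
        row = {"participant_id": rec["participant_id"]}
        for c in COMPONENTS:
            row[c] = getattr(profile, c)
        row["component_count"] = profile.component_count
        row["ms_idf"] = profile.ms_idf
        row["complete"] = profile.complete
        rows.append(row)
    return pd.DataFrame(rows)
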