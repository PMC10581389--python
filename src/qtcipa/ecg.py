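"""QT correction and sex-specific QTc threshold banding.

Four standard heart-rate corrections are supported — Bazett (QT/RR^1/2),
Fridericia (QT/RR^1/3), Framingham (QT + 154·(1−RR)) and Hodges
(QT + 1.75·(HR−60)) — plus a pass-through for a pre-corrected QTc.  All
four agree at RR = 1 s (60 bpm).  No single formula is mandated by the
underlying algorithm, so the choice is explicit and recorded in the
decision trace; the package default is Fridericia, which over- and
under-corrects less than Bazett at high and low heart rates.

The management bands follow the antipsychotic QTc-management table:
below the sex-specific normal upper limit (440 ms men / 470 ms women) no
action is required unless T-wave morphology is abnormal; between that
limit and 500 ms, consider dose reduction or switching (cardiology
review to consider); at or above 500 ms, stop the suspected causative
drug(s) and obtain immediate cardiology review.  A QTc exactly at the
sex limit is treated as PROLONGED and exactly 500 ms as CRITICAL — the
conservative reading of the boundary in each case.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .scoring import Sex

__all__ = [
    "CorrectionFormula",
    "QtcBand",
    "Referral",
    "EcgMeasurement",
    "ThresholdPolicy",
    "QtcAssessment",
    "correct_qt",
    "assess_qtc",
]


class CorrectionFormula(str, Enum):
    bazett = "bazett"
    fridericia = "fridericia"
    framingham = "framingham"
    hodges = "hodges"
    precorrected = "precorrected"


class QtcBand(str, Enum):
    NORMAL = "NORMAL"
    PROLONGED = "PROLONGED"
    CRITICAL = "CRITICAL"


class Referral(str, Enum):
    NONE = "NONE"
    CONSIDER = "CONSIDER"
    IMMEDIATE = "IMMEDIATE"


class EcgMeasurement(BaseModel):
    """A QT measurement with rate information or a pre-corrected QTc.

    ``rr_s`` and ``heart_rate_bpm`` are mutually derivable
    (rr_s = 60 / heart_rate_bpm); either may be supplied.
    """

    qt_ms: Optional[float] = Field(default=None, gt=0, lt=1000)
    rr_s: Optional[float] = Field(default=None, gt=0.2, lt=3)
    heart_rate_bpm: Optional[float] = Field(default=None, gt=20, lt=300)
    qtc_ms: Optional[float] = Field(default=None, gt=0)
    correction_formula: CorrectionFormula = CorrectionFormula.fridericia

    @model_validator(mode="after")
    def _sufficient(self) -> "EcgMeasurement":
        if self.rr_s is None and self.heart_rate_bpm is not None:
            object.__setattr__(self, "rr_s", 60.0 / self.heart_rate_bpm)
        elif self.heart_rate_bpm is None and self.rr_s is not None:
            object.__setattr__(self, "heart_rate_bpm", 60.0 / self.rr_s)
        if self.qtc_ms is None and (self.qt_ms is None or self.rr_s is None):
            raise ValueError(
                "need either qtc_ms or qt_ms together with rate information"
            )
        return self


class ThresholdPolicy(BaseModel):
    """Sex-specific QTc normal upper limits and the critical cutoff (ms)."""

    male_normal_upper_ms: float = 440
    female_normal_upper_ms: float = 470
    critical_ms: float = 500

    @model_validator(mode="after")
    def _ordered(self) -> "ThresholdPolicy":
        if not (
            self.male_normal_upper_ms < self.critical_ms
            and self.female_normal_upper_ms < self.critical_ms
        ):
            raise ValueError("normal upper limits must be below the critical cutoff")
        return self


# Action text mirroring the management table, one row per band.
_ACTIONS = {
    QtcBand.NORMAL: "No action required unless abnormal T-wave morphology; "
    "consider cardiac review if in doubt.",
    QtcBand.PROLONGED: "Consider reducing dose or switching to drug of lower effect.",
    QtcBand.CRITICAL: "Stop suspected causative drug(s) and switch to drug with a "
    "lower effect. Immediate cardiology review is needed.",
}

_REFERRALS = {
    QtcBand.NORMAL: Referral.NONE,
    QtcBand.PROLONGED: Referral.CONSIDER,
    QtcBand.CRITICAL: Referral.IMMEDIATE,
}


class QtcAssessment(BaseModel):
    qtc_ms: float
    band: QtcBand
    action: str
    cardiology_referral: Referral


def correct_qt(measurement: EcgMeasurement) -> float:
    """Heart-rate-corrected QT in milliseconds.

    Bazett and Fridericia divide by RR^1/2 and RR^1/3 (RR in seconds);
    Framingham and Hodges are linear in RR and heart rate respectively.
    ``precorrected`` passes ``qtc_ms`` through unchanged.
    """
    f = measurement.correction_formula
    if f is CorrectionFormula.precorrected:
        if measurement.qtc_ms is None:
            raise ValueError("precorrected formula requires qtc_ms")
        return measurement.qtc_ms
    if measurement.qt_ms is None or measurement.rr_s is None:
        raise ValueError(f"{f.value} correction requires qt_ms and rate information")
    qt, rr = measurement.qt_ms, measurement.rr_s
    if f is CorrectionFormula.bazett:
        return qt / math.sqrt(rr)
    if f is CorrectionFormula.fridericia:
        return qt / rr ** (1.0 / 3.0)
    if f is CorrectionFormula.framingham:
        return qt + 154.0 * (1.0 - rr)
    if f is CorrectionFormula.hodges:
        return qt + 1.75 * (60.0 / rr - 60.0)
    raise ValueError(f"unknown correction formula: {f}")  # pragma: no cover


def assess_qtc(
    qtc_ms: float, sex: Sex, policy: ThresholdPolicy | None = None
) -> QtcAssessment:
    """Band a QTc value against the sex-specific policy and attach the action.

    NORMAL strictly below the sex limit; PROLONGED from the sex limit up
    to (not including) the critical cutoff; CRITICAL at or above it.
    """
    policy = policy or ThresholdPolicy()
    if not (200 < qtc_ms < 800):
        raise ValueError(f"qtc_ms out of plausible range (200, 800): {qtc_ms}")
    upper = (
        policy.male_normal_upper_ms if sex is Sex.male else policy.female_normal_upper_ms
    )
    if qtc_ms >= policy.critical_ms:
        band = QtcBand.CRITICAL
    elif qtc_ms >= upper:
        band = QtcBand.PROLONGED
    else:
        band = QtcBand.NORMAL
    return QtcAssessment(
        qtc_ms=qtc_ms,
        band=band,
        action=_ACTIONS[band],
        cardiology_referral=_REFERRALS[band],
    )
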