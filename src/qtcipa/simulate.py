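"""Synthetic patients and simulated rater panels.

Everything the package tests against is generated here, so no external
data are required.  Two generators:

* :func:`generate_patients` draws a cohort of synthetic psychiatric-care
  patients with configurable risk-factor prevalences, per-sex QTc
  distributions (truncated normal within 300–700 ms) and medication
  lists sampled from a risk catalog.  Defaults sketch a mixed adult
  inpatient/outpatient mental-health population: modest comorbidity
  prevalences, QTc centred in the normal range with the usual ~20–25 ms
  spread, and ECGs available for about half of patients.

* :func:`simulate_ratings` draws a raters × items Likert matrix under
  the minimal generative model for a content-validity panel: each
  present cell independently falls in {3, 4} (agreement) with
  probability ``p_agree`` and in {1, 2} otherwise, with cells missing
  independently with probability ``p_missing``.  Under this model the
  I-CVI is an unbiased estimator of ``p_agree``, which gives the
  recovery checks a closed-form target.  Defaults mirror a 30-rater,
  8-item panel.

Both are deterministic under a fixed seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator
from scipy import stats

from .catalog import RiskCatalog, load_default_catalog
from .ecg import CorrectionFormula, EcgMeasurement
from .engine import MedicationRecord, PatientProfile
from .scoring import RiskFactorInputs, Sex
from .validity import RatingMatrix

__all__ = [
    "PatientSimConfig",
    "SurveySimConfig",
    "generate_patients",
    "simulate_ratings",
]

_QTC_LO, _QTC_HI = 300.0, 700.0

DEFAULT_PREVALENCE = {
    "on_loop_diuretic": 0.10,
    "acute_mi": 0.02,
    "sepsis": 0.02,
    "heart_failure": 0.05,
    "hypokalemia": 0.10,
    "pk_inhibitor_present": 0.10,
}


class PatientSimConfig(BaseModel):
    n_patients: int = Field(default=100, ge=0)
    seed: int = 0
    prevalence: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    qtc_mean_ms: dict[str, float] = Field(
        default_factory=lambda: {"male": 415.0, "female": 425.0}
    )
    qtc_sd_ms: float = Field(default=22.0, gt=0)
    p_ecg_available: float = Field(default=0.5, ge=0, le=1)
    p_female: float = Field(default=0.5, ge=0, le=1)
    mean_n_medications: float = Field(default=1.5, ge=0)

    @field_validator("prevalence")
    @classmethod
    def _probabilities(cls, v: dict[str, float]) -> dict[str, float]:
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence[{k!r}] must be in [0, 1]")
        return v


class SurveySimConfig(BaseModel):
    n_raters: int = Field(default=30, ge=1)
    n_items: int = Field(default=8, ge=1)
    p_agree: float = Field(default=0.93, ge=0, le=1)
    p_missing: float = Field(default=0.0, ge=0, le=1)
    seed: int = 0
    attribute: str = "appropriateness"


def _truncnorm(rng: np.random.Generator, mean: float, sd: float) -> float:
    a, b = (_QTC_LO - mean) / sd, (_QTC_HI - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_patients(
    config: PatientSimConfig, catalog: Optional[RiskCatalog] = None
) -> list[PatientProfile]:
    """Draw a reproducible synthetic cohort.

    Binary risk factors are independent Bernoulli draws at the
    configured prevalences; medication counts are Poisson; QTc values
    (when an ECG is available) are per-sex truncated normals supplied
    pre-corrected.
    """
    rng = np.random.default_rng(config.seed)
    catalog = catalog or load_default_catalog()
    drug_names = [e.drug_name for e in catalog.entries]
    patients: list[PatientProfile] = []
    prev = {**DEFAULT_PREVALENCE, **config.prevalence}
    for i in range(config.n_patients):
        sex = Sex.female if rng.random() < config.p_female else Sex.male
        age = float(np.clip(rng.normal(45, 16), 18, 95))
        flags = {k: bool(rng.random() < p) for k, p in prev.items()}
        potassium = (
            float(np.clip(rng.normal(3.2, 0.2), 2.5, 3.5))
            if flags["hypokalemia"]
            else float(np.clip(rng.normal(4.2, 0.35), 3.6, 5.5))
        )
        n_meds = int(rng.poisson(config.mean_n_medications))
        meds = tuple(
            MedicationRecord(
                name=drug_names[int(rng.integers(len(drug_names)))],
                is_metabolic_inhibitor=bool(
                    rng.random() < prev["pk_inhibitor_present"]
                ),
            )
            for _ in range(n_meds)
        )
        ecg = None
        if rng.random() < config.p_ecg_available:
            qtc = _truncnorm(rng, config.qtc_mean_ms[sex.value], config.qtc_sd_ms)
            ecg = EcgMeasurement(
                qtc_ms=qtc, correction_formula=CorrectionFormula.precorrected
            )
        inputs = RiskFactorInputs(
            age_years=age,
            sex=sex,
            serum_potassium_mmol_per_L=potassium,
            on_loop_diuretic=flags["on_loop_diuretic"],
            acute_mi=flags["acute_mi"],
            sepsis=flags["sepsis"],
            heart_failure=flags["heart_failure"],
            baseline_qtc_ms=ecg.qtc_ms if ecg is not None else None,
            pk_inhibitor_present=flags["pk_inhibitor_present"],
        )
        patients.append(
            PatientProfile(
                patient_id=f"sim-{config.seed}-{i:05d}",
                risk_inputs=inputs,
                medications=meds,
                ecg=ecg,
            )
        )
    return patients


def simulate_ratings(config: SurveySimConfig) -> RatingMatrix:
    """Draw a raters × items Likert matrix under independent agreement.

    Each present cell is 3 or 4 (equiprobable) with probability
    ``p_agree``, else 1 or 2; cells go missing independently with
    probability ``p_missing``.  An item left with no ratings at all is
    re-drawn (bounded retries) so the matrix invariant holds.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_raters, config.n_items)
    agree = rng.random(shape) < config.p_agree
    high = rng.integers(0, 2, size=shape)  # picks within {3,4} or {1,2}
    ratings = np.where(agree, 3 + high, 1 + high).astype(float)
    if config.p_missing > 0:
        missing = rng.random(shape) < config.p_missing
        # an all-missing column violates the matrix invariant: re-draw it
        for _ in range(100):
            bad = missing.all(axis=0)
            if not bad.any():
                break
            missing[:, bad] = rng.random((config.n_raters, int(bad.sum()))) < config.p_missing
        else:
            # p_missing so high that retries keep failing: keep one rating
            for j in np.where(missing.all(axis=0))[0]:
                missing[int(rng.integers(config.n_raters)), j] = False
        ratings[missing] = np.nan
    raters = [f"R{i + 1:02d}" for i in range(config.n_raters)]
    items = [f"Q{j + 1}" for j in range(config.n_items)]
    return RatingMatrix(ratings, raters, items, attribute=config.attribute)
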