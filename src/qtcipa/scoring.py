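"""Additive QTc-prolongation risk score and drug-interaction assessment.

The algorithm's third step assigns each patient an additive points total
(a Tisdale-style score): every asserted risk factor contributes a fixed,
non-negative number of points and the total routes the patient either to
the recommend-therapy path (below the ECG trigger) or to the baseline-ECG
path (at or above it).  The point constants live in a config file, not in
code — see ``data/default_config.yaml`` — while this module owns the
predicate for each factor id and the additive machinery.

Missing optional labs (potassium, baseline QTc) contribute zero points
but are reported as *not assessed*: a decision aid must distinguish
"normal" from "unknown".

A score of exactly 7 points routes to the baseline-ECG path.  The
algorithm's wording claims 7 for both paths ("≤ 7" recommend, "≥ 7"
baseline ECG); the engine resolves the tie conservatively — more
monitoring — which also matches the cited score's moderate-risk band
starting at 7.
"""

from __future__ import annotations

from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .catalog import RiskCatalog, RiskCategory, count_qt_drugs

__all__ = [
    "Sex",
    "Stratum",
    "RiskFactorInputs",
    "PointsFactor",
    "PointsTable",
    "Contribution",
    "RiskScoreResult",
    "InteractionAssessment",
    "compute_risk_score",
    "stratify",
    "assess_interactions",
    "effective_qt_drug_count",
    "load_points_table",
    "load_default_config",
    "FACTOR_PREDICATES",
]


class Sex(str, Enum):
    male = "male"
    female = "female"


class Stratum(str, Enum):
    LOW = "LOW"
    ELEVATED = "ELEVATED"


class RiskFactorInputs(BaseModel):
    """Patient-level inputs to the additive risk score.

    ``qt_drug_count`` is the number of QT-risk drugs the patient is on
    (known + possible + conditional-with-condition-asserted), normally
    produced by :func:`effective_qt_drug_count` and including the
    proposed drug.
    """

    age_years: float = Field(ge=0, lt=150)
    sex: Sex
    serum_potassium_mmol_per_L: Optional[float] = Field(default=None, gt=1, lt=10)
    on_loop_diuretic: bool = False
    acute_mi: bool = False
    sepsis: bool = False
    heart_failure: bool = False
    baseline_qtc_ms: Optional[float] = Field(default=None, gt=200, lt=800)
    qt_drug_count: int = Field(default=0, ge=0)
    pk_inhibitor_present: bool = False


# Each predicate returns True/False, or None when the factor cannot be
# assessed because an optional measurement is absent.
FACTOR_PREDICATES: dict[str, Callable[[RiskFactorInputs], Optional[bool]]] = {
    "age_ge_68": lambda x: x.age_years >= 68,
    "female_sex": lambda x: x.sex is Sex.female,
    "loop_diuretic": lambda x: x.on_loop_diuretic,
    "hypokalemia": lambda x: (
        None
        if x.serum_potassium_mmol_per_L is None
        else x.serum_potassium_mmol_per_L <= 3.5
    ),
    "baseline_qtc_ge_450": lambda x: (
        None if x.baseline_qtc_ms is None else x.baseline_qtc_ms >= 450
    ),
    "acute_mi": lambda x: x.acute_mi,
    "sepsis": lambda x: x.sepsis,
    "heart_failure": lambda x: x.heart_failure,
    "one_qt_drug": lambda x: x.qt_drug_count >= 1,
    "additional_qt_drugs": lambda x: x.qt_drug_count >= 2,
}


class PointsFactor(BaseModel):
    id: str
    description: str
    points: int = Field(ge=0)


class PointsTable(BaseModel):
    """Ordered factor/points rows plus the score thresholds.

    ``ecg_trigger_threshold`` is the total at or above which the patient
    is routed to the baseline-ECG path (default 7); ``high_threshold``
    optionally marks the cited score's high-risk band.
    """

    factors: tuple[PointsFactor, ...]
    ecg_trigger_threshold: int = Field(default=7, gt=0)
    high_threshold: Optional[int] = None

    @model_validator(mode="after")
    def _known_factors(self) -> "PointsTable":
        seen: set[str] = set()
        for f in self.factors:
            if f.id not in FACTOR_PREDICATES:
                raise ValueError(f"unknown risk factor id: {f.id!r}")
            if f.id in seen:
                raise ValueError(f"duplicate risk factor id: {f.id!r}")
            seen.add(f.id)
        return self


class Contribution(BaseModel):
    factor_id: str
    points_awarded: int
    status: str  # "met", "not_met", or "not assessed"


class RiskScoreResult(BaseModel):
    total_points: int = Field(ge=0)
    contributions: tuple[Contribution, ...]
    stratum: Stratum

    @model_validator(mode="after")
    def _total_consistent(self) -> "RiskScoreResult":
        if self.total_points != sum(c.points_awarded for c in self.contributions):
            raise ValueError("total_points must equal the sum of contributions")
        return self


class InteractionAssessment(BaseModel):
    """Step-2 drug-interaction summary.

    Pharmacodynamic stacking (two or more QT-risk drugs) and
    pharmacokinetic interaction (a metabolic inhibitor co-prescribed)
    are kept as two separate, explicitly defined flags; neither alters
    the score silently — both surface in the report.
    """

    qt_drug_count_by_category: dict[RiskCategory, int]
    pharmacodynamic_stack_flag: bool
    pharmacokinetic_flag: bool
    notes: tuple[str, ...] = ()


def compute_risk_score(inputs: RiskFactorInputs, table: PointsTable) -> RiskScoreResult:
    """Evaluate every factor row of *table* against *inputs* and sum.

    Deterministic; each factor contributes at most once; a factor whose
    predicate needs a missing optional measurement awards 0 points with
    status ``"not assessed"``.
    """
    contributions: list[Contribution] = []
    total = 0
    for factor in table.factors:
        outcome = FACTOR_PREDICATES[factor.id](inputs)
        if outcome is None:
            contributions.append(
                Contribution(factor_id=factor.id, points_awarded=0, status="not assessed")
            )
        elif outcome:
            total += factor.points
            contributions.append(
                Contribution(factor_id=factor.id, points_awarded=factor.points, status="met")
            )
        else:
            contributions.append(
                Contribution(factor_id=factor.id, points_awarded=0, status="not_met")
            )
    return RiskScoreResult(
        total_points=total,
        contributions=tuple(contributions),
        stratum=stratify(total, table),
    )


def stratify(total_points: int, table: PointsTable) -> Stratum:
    """ELEVATED iff the total reaches the ECG trigger threshold (default 7)."""
    if total_points < 0:
        raise ValueError("total_points must be non-negative")
    return (
        Stratum.ELEVATED
        if total_points >= table.ecg_trigger_threshold
        else Stratum.LOW
    )


def effective_qt_drug_count(
    counts: dict[RiskCategory, int], conditional_triggers_present: bool
) -> int:
    """QT-risk drug count feeding the score and the stacking flag.

    Known- and possible-risk drugs always count; conditional-risk drugs
    count only when the patient asserts the triggering condition.
    """
    n = counts.get(RiskCategory.KNOWN_RISK, 0) + counts.get(RiskCategory.POSSIBLE_RISK, 0)
    if conditional_triggers_present:
        n += counts.get(RiskCategory.CONDITIONAL_RISK, 0)
    return n


def assess_interactions(
    medications: Iterable["MedicationRecord"],
    catalog: RiskCatalog,
    conditional_triggers_present: bool = False,
) -> InteractionAssessment:
    """Step-2 assessment of dose, route and drug interactions."""
    meds = list(medications)
    counts = count_qt_drugs(catalog, [m.name for m in meds])
    stack_count = effective_qt_drug_count(counts, conditional_triggers_present)
    pk_flag = any(m.is_metabolic_inhibitor for m in meds)
    notes: list[str] = []
    if counts.get(RiskCategory.CONDITIONAL_RISK, 0) and not conditional_triggers_present:
        notes.append(
            "Conditional-risk drug present; counts toward the QT-drug stack "
            "only if its triggering condition applies."
        )
    for m in meds:
        if m.route is not None and m.route == "intravenous":
            notes.append(
                f"{m.name}: intravenous route — higher peak exposure; use caution."
            )
        if m.dose_text and "supratherapeutic" in m.dose_text.lower():
            notes.append(f"{m.name}: supratherapeutic dose noted — use caution.")
    if stack_count >= 2:
        notes.append(
            "Pharmacodynamic interaction: two or more QT-risk drugs co-prescribed."
        )
    if pk_flag:
        notes.append(
            "Pharmacokinetic interaction: metabolic inhibitor co-prescribed may "
            "raise QT-drug exposure."
        )
    return InteractionAssessment(
        qt_drug_count_by_category=counts,
        pharmacodynamic_stack_flag=stack_count >= 2,
        pharmacokinetic_flag=pk_flag,
        notes=tuple(notes),
    )


def _config_text(path: str | Path | None) -> str:
    if path is None:
        ref = resources.files("qtcipa.data").joinpath("default_config.yaml")
        return ref.read_text(encoding="utf-8")
    return Path(path).read_text(encoding="utf-8")


def load_default_config(path: str | Path | None = None) -> dict:
    """Parse the engine config (points table + ECG thresholds + triggers)."""
    cfg = yaml.safe_load(_config_text(path))
    if not isinstance(cfg, dict) or "points_table" not in cfg:
        raise ValueError("config must contain a points_table block")
    return cfg


def load_points_table(path: str | Path | None = None) -> PointsTable:
    """Load the points table from a YAML config (bundled default if None)."""
    cfg = load_default_config(path)
    block = cfg["points_table"]
    thresholds = block.get("thresholds", {})
    return PointsTable(
        factors=tuple(PointsFactor(**f) for f in block["factors"]),
        ecg_trigger_threshold=thresholds.get("ecg_trigger", 7),
        high_threshold=thresholds.get("high"),
    )
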