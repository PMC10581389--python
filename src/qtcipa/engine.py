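"""The eight-step QTc-prolongation decision algorithm (Q1–Q8).

Routing a patient and a proposed drug through the steps:

* **Q1** — classify the proposed drug by TdP risk category.  A drug in
  no risk category short-circuits to RECOMMEND: no QTc-specific risk is
  identified, though general prescribing caution still applies.
* **Q2** — assess dose, route and drug interactions (pharmacodynamic
  stacking of QT-risk drugs; pharmacokinetic inhibitor co-prescription).
  These annotate the rationale; the algorithm attaches no point values
  to them.
* **Q3/Q4** — compute the additive risk score, proposed drug included,
  and decide whether ECG monitoring is needed.
* **Q5** — score below the trigger (7 points): recommend therapy.
* **Q6** — score at/above the trigger with no ECG available: obtain a
  baseline ECG before deciding.
* **Q7** — ECG shows QTc at/above the critical cutoff (500 ms): avoid
  therapy and refer to cardiology immediately.
* **Q8** — ECG below the cutoff: recommend therapy with follow-up ECG
  and physical exam; the dose-reduction/switch caution is appended when
  the QTc band is PROLONGED.

Every run emits a complete, ordered audit trail of the steps taken, so
a reviewer can reconstruct exactly why a verdict was reached.
"""

from __future__ import annotations

import json
from enum import Enum
from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .catalog import RiskCatalog, RiskCategory, classify_drug, count_qt_drugs
from .ecg import (
    EcgMeasurement,
    QtcAssessment,
    QtcBand,
    ThresholdPolicy,
    assess_qtc,
    correct_qt,
)
from .scoring import (
    InteractionAssessment,
    PointsTable,
    RiskFactorInputs,
    RiskScoreResult,
    Stratum,
    assess_interactions,
    compute_risk_score,
    effective_qt_drug_count,
)

__all__ = [
    "Route",
    "Verdict",
    "MedicationRecord",
    "PatientProfile",
    "TraceStep",
    "DecisionTrace",
    "Recommendation",
    "route_decision",
    "run_algorithm",
    "render_report",
    "VERDICT_SEVERITY",
    "DEFAULT_MONITORING_TRIGGERS",
]

DEFAULT_MONITORING_TRIGGERS = ("prolonged_band", "dose_escalation", "second_qt_drug")


class Route(str, Enum):
    oral = "oral"
    intravenous = "intravenous"
    other = "other"


class Verdict(str, Enum):
    RECOMMEND = "RECOMMEND"
    RECOMMEND_WITH_MONITORING = "RECOMMEND_WITH_MONITORING"
    OBTAIN_BASELINE_ECG = "OBTAIN_BASELINE_ECG"
    AVOID_AND_REFER = "AVOID_AND_REFER"


# Restrictiveness ordering used by the monotonicity property: increasing
# risk never moves the verdict to a less restrictive one.
VERDICT_SEVERITY = {
    Verdict.RECOMMEND: 0,
    Verdict.RECOMMEND_WITH_MONITORING: 1,
    Verdict.OBTAIN_BASELINE_ECG: 2,
    Verdict.AVOID_AND_REFER: 3,
}


class MedicationRecord(BaseModel):
    name: str = Field(min_length=1)
    dose_text: Optional[str] = None
    route: Optional[Route] = None
    is_metabolic_inhibitor: bool = False


class PatientProfile(BaseModel):
    """Aggregated input to the decision engine.

    ``conditional_triggers_present`` asserts that the triggering
    condition of any conditional-risk drug applies to this patient
    (e.g. the electrolyte disturbance or overdose the listing is
    conditioned on); only then do conditional-risk drugs count toward
    the QT-drug stack.
    """

    patient_id: str
    risk_inputs: RiskFactorInputs
    medications: tuple[MedicationRecord, ...] = ()
    ecg: Optional[EcgMeasurement] = None
    conditional_triggers_present: bool = False


class TraceStep(BaseModel):
    step_id: str  # Q1..Q8
    input_summary: str
    outcome: str


_STEP_ORDER = {f"Q{i}": i for i in range(1, 9)}


class DecisionTrace(BaseModel):
    steps: tuple[TraceStep, ...]

    @model_validator(mode="after")
    def _ordered_unique(self) -> "DecisionTrace":
        ids = [s.step_id for s in self.steps]
        if len(set(ids)) != len(ids):
            raise ValueError("each step appears at most once in a trace")
        order = [_STEP_ORDER[i] for i in ids]
        if order != sorted(order):
            raise ValueError("trace steps must appear in algorithm order")
        return self


class Recommendation(BaseModel):
    verdict: Verdict
    rationale: tuple[str, ...]
    trace: DecisionTrace
    qtc_assessment: Optional[QtcAssessment] = None
    risk_score: Optional[RiskScoreResult] = None
    interactions: Optional[InteractionAssessment] = None

    @model_validator(mode="after")
    def _invariants(self) -> "Recommendation":
        if not self.trace.steps:
            raise ValueError("trace must be non-empty")
        if self.verdict is Verdict.AVOID_AND_REFER:
            if self.qtc_assessment is None or self.qtc_assessment.band is not QtcBand.CRITICAL:
                raise ValueError(
                    "AVOID_AND_REFER requires a critical QTc assessment"
                )
        return self


def route_decision(
    category: RiskCategory,
    total_points: int,
    qtc_assessment: Optional[QtcAssessment],
    ecg_trigger_threshold: int = 7,
    critical_ms: float = 500,
) -> Verdict:
    """Pure terminal-verdict routing shared by :func:`run_algorithm`.

    Inputs are the Q1 classification, the Q3 score and the Q6–Q8 ECG
    assessment (None when no ECG is available).
    """
    if category is RiskCategory.NOT_LISTED:
        return Verdict.RECOMMEND
    if total_points < ecg_trigger_threshold:
        return Verdict.RECOMMEND
    if qtc_assessment is None:
        return Verdict.OBTAIN_BASELINE_ECG
    if qtc_assessment.qtc_ms >= critical_ms:
        return Verdict.AVOID_AND_REFER
    return Verdict.RECOMMEND_WITH_MONITORING


def run_algorithm(
    patient: PatientProfile,
    proposed_drug: str,
    catalog: RiskCatalog,
    table: Optional[PointsTable] = None,
    policy: Optional[ThresholdPolicy] = None,
    *,
    monitoring_triggers: Sequence[str] = DEFAULT_MONITORING_TRIGGERS,
    dose_escalation: bool = False,
) -> Recommendation:
    """Run the eight decision steps and return a traced recommendation.

    Deterministic: the same inputs always yield the same verdict, and
    clinical edge values (boundary scores, boundary QTc) never raise.
    """
    from .scoring import load_points_table

    table = table or load_points_table()
    policy = policy or ThresholdPolicy()
    steps: list[TraceStep] = []
    rationale: list[str] = []

    # Q1 — drug classification
    category = classify_drug(catalog, proposed_drug)
    steps.append(
        TraceStep(
            step_id="Q1",
            input_summary=f"proposed drug: {proposed_drug}",
            outcome=f"risk category {category.value}",
        )
    )
    if category is RiskCategory.NOT_LISTED:
        rationale.append(
            f"{proposed_drug} is in no TdP risk category of the loaded catalog: "
            "no QTc-specific risk identified. General prescribing caution and "
            "clinical judgment still apply."
        )
        return Recommendation(
            verdict=Verdict.RECOMMEND,
            rationale=tuple(rationale),
            trace=DecisionTrace(steps=tuple(steps)),
        )
    rationale.append(f"{proposed_drug}: {category.value.replace('_', ' ').lower()} of TdP.")

    # Q2 — dose, route, interactions (proposed drug included)
    meds = list(patient.medications) + [MedicationRecord(name=proposed_drug)]
    interactions = assess_interactions(
        meds, catalog, patient.conditional_triggers_present
    )
    steps.append(
        TraceStep(
            step_id="Q2",
            input_summary=f"{len(meds)} medication(s) incl. proposed",
            outcome=(
                f"PD stack={interactions.pharmacodynamic_stack_flag}, "
                f"PK inhibitor={interactions.pharmacokinetic_flag}"
            ),
        )
    )
    rationale.extend(interactions.notes)

    # Q3 — risk score with the proposed drug counted
    qt_count = effective_qt_drug_count(
        interactions.qt_drug_count_by_category, patient.conditional_triggers_present
    )
    inputs = patient.risk_inputs.model_copy(update={"qt_drug_count": qt_count})
    score = compute_risk_score(inputs, table)
    steps.append(
        TraceStep(
            step_id="Q3",
            input_summary=f"QT-drug count {qt_count}",
            outcome=f"risk score {score.total_points} ({score.stratum.value})",
        )
    )
    not_assessed = [c.factor_id for c in score.contributions if c.status == "not assessed"]
    if not_assessed:
        rationale.append(
            "Not assessed (missing data, contributed 0 points): "
            + ", ".join(not_assessed)
            + "."
        )

    # Q4 — need for ECG monitoring based on the score
    steps.append(
        TraceStep(
            step_id="Q4",
            input_summary=f"score {score.total_points} vs trigger {table.ecg_trigger_threshold}",
            outcome="ECG monitoring needed"
            if score.stratum is Stratum.ELEVATED
            else "no ECG required by score",
        )
    )

    if score.stratum is Stratum.LOW:
        # Q5 — recommend therapy
        steps.append(
            TraceStep(
                step_id="Q5",
                input_summary=f"score {score.total_points} < {table.ecg_trigger_threshold}",
                outcome="recommend therapy",
            )
        )
        rationale.append(
            f"Risk score {score.total_points} is below the ECG trigger "
            f"({table.ecg_trigger_threshold} points): therapy recommended."
        )
        return Recommendation(
            verdict=Verdict.RECOMMEND,
            rationale=tuple(rationale),
            trace=DecisionTrace(steps=tuple(steps)),
            risk_score=score,
            interactions=interactions,
        )

    # Q6 — baseline ECG required
    if patient.ecg is None:
        steps.append(
            TraceStep(
                step_id="Q6",
                input_summary="no ECG available",
                outcome="obtain baseline ECG before deciding",
            )
        )
        rationale.append(
            f"Risk score {score.total_points} reaches the ECG trigger "
            f"({table.ecg_trigger_threshold} points) and no ECG is available: "
            "obtain a baseline ECG before initiating therapy."
        )
        return Recommendation(
            verdict=Verdict.OBTAIN_BASELINE_ECG,
            rationale=tuple(rationale),
            trace=DecisionTrace(steps=tuple(steps)),
            risk_score=score,
            interactions=interactions,
        )

    qtc = correct_qt(patient.ecg)
    assessment = assess_qtc(qtc, patient.risk_inputs.sex, policy)
    steps.append(
        TraceStep(
            step_id="Q6",
            input_summary=(
                f"ECG available ({patient.ecg.correction_formula.value} correction)"
            ),
            outcome=f"QTc {qtc:.0f} ms, band {assessment.band.value}",
        )
    )

    if qtc >= policy.critical_ms:
        # Q7 — avoid and refer
        steps.append(
            TraceStep(
                step_id="Q7",
                input_summary=f"QTc {qtc:.0f} ms >= {policy.critical_ms:.0f} ms",
                outcome="avoid therapy, consider cardiac consultation",
            )
        )
        rationale.append(
            f"QTc {qtc:.0f} ms meets the critical cutoff "
            f"({policy.critical_ms:.0f} ms): avoid therapy and consider cardiac "
            "consultation."
        )
        rationale.append(assessment.action)
        return Recommendation(
            verdict=Verdict.AVOID_AND_REFER,
            rationale=tuple(rationale),
            trace=DecisionTrace(steps=tuple(steps)),
            qtc_assessment=assessment,
            risk_score=score,
            interactions=interactions,
        )

    # Q8 — recommend with monitoring
    steps.append(
        TraceStep(
            step_id="Q8",
            input_summary=f"QTc {qtc:.0f} ms < {policy.critical_ms:.0f} ms",
            outcome="recommend therapy with follow-up ECG and physical exam",
        )
    )
    rationale.append(
        f"QTc {qtc:.0f} ms is below the critical cutoff: therapy recommended "
        "with follow-up ECG and physical exam."
    )
    triggered = []
    if "prolonged_band" in monitoring_triggers and assessment.band is QtcBand.PROLONGED:
        triggered.append("QTc band PROLONGED")
        rationale.append(assessment.action)
    if "dose_escalation" in monitoring_triggers and dose_escalation:
        triggered.append("dose escalation planned")
    second_drug = (
        effective_qt_drug_count(
            interactions.qt_drug_count_by_category, patient.conditional_triggers_present
        )
        >= 2
    )
    if "second_qt_drug" in monitoring_triggers and second_drug:
        triggered.append("second QT-risk drug present")
    if triggered:
        rationale.append(
            "Follow-up monitoring advised (" + "; ".join(triggered) + ")."
        )
    return Recommendation(
        verdict=Verdict.RECOMMEND_WITH_MONITORING,
        rationale=tuple(rationale),
        trace=DecisionTrace(steps=tuple(steps)),
        qtc_assessment=assessment,
        risk_score=score,
        interactions=interactions,
    )


def render_report(rec: Recommendation, format: str = "text") -> str:
    """Render a recommendation as ``text``, ``json`` or ``markdown``.

    The JSON form round-trips losslessly through
    ``Recommendation.model_validate_json``.
    """
    if format == "json":
        return rec.model_dump_json(indent=2)
    lines: list[str] = []
    h1 = "# " if format == "markdown" else ""
    h2 = "## " if format == "markdown" else ""
    bullet = "- " if format == "markdown" else "  * "
    lines.append(f"{h1}QTc prolongation assessment")
    lines.append(f"Verdict: {rec.verdict.value}")
    lines.append("")
    lines.append(f"{h2}Rationale")
    for r in rec.rationale:
        lines.append(f"{bullet}{r}")
    if rec.risk_score is not None:
        lines.append("")
        lines.append(
            f"{h2}Risk score: {rec.risk_score.total_points} points "
            f"({rec.risk_score.stratum.value})"
        )
        for c in rec.risk_score.contributions:
            lines.append(f"{bullet}{c.factor_id}: {c.points_awarded} ({c.status})")
    if rec.qtc_assessment is not None:
        lines.append("")
        lines.append(
            f"{h2}QTc: {rec.qtc_assessment.qtc_ms:.0f} ms — band "
            f"{rec.qtc_assessment.band.value}, cardiology referral "
            f"{rec.qtc_assessment.cardiology_referral.value}"
        )
        lines.append(f"{bullet}{rec.qtc_assessment.action}")
    lines.append("")
    lines.append(f"{h2}Decision trace")
    for s in rec.trace.steps:
        lines.append(f"{bullet}{s.step_id}: {s.input_summary} -> {s.outcome}")
    return "\n".join(lines)
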