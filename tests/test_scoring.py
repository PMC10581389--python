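"""Additive risk score: additivity, monotonicity, oracle equivalence."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtcipa.catalog import RiskCategory
from qtcipa.engine import MedicationRecord
from qtcipa.scoring import (
    PointsFactor,
    PointsTable,
    RiskFactorInputs,
    Sex,
    Stratum,
    assess_interactions,
    compute_risk_score,
    stratify,
)


def _inputs(**kw):
    base = dict(age_years=40, sex=Sex.male)
    base.update(kw)
    return RiskFactorInputs(**base)


# Independent re-statement of the Tisdale factor predicates, used only to
# cross-check compute_risk_score; deliberately not imported from the package.
def oracle_points(x: RiskFactorInputs, table: PointsTable) -> int:
    pts = {f.id: f.points for f in table.factors}
    total = 0
    if x.age_years >= 68:
        total += pts.get("age_ge_68", 0)
    if x.sex is Sex.female:
        total += pts.get("female_sex", 0)
    if x.on_loop_diuretic:
        total += pts.get("loop_diuretic", 0)
    if x.serum_potassium_mmol_per_L is not None and x.serum_potassium_mmol_per_L <= 3.5:
        total += pts.get("hypokalemia", 0)
    if x.baseline_qtc_ms is not None and x.baseline_qtc_ms >= 450:
        total += pts.get("baseline_qtc_ge_450", 0)
    if x.acute_mi:
        total += pts.get("acute_mi", 0)
    if x.sepsis:
        total += pts.get("sepsis", 0)
    if x.heart_failure:
        total += pts.get("heart_failure", 0)
    if x.qt_drug_count >= 1:
        total += pts.get("one_qt_drug", 0)
    if x.qt_drug_count >= 2:
        total += pts.get("additional_qt_drugs", 0)
    return total


class TestComputeRiskScore:
    def test_no_factors_no_optionals_scores_zero(self, points_table):
        res = compute_risk_score(_inputs(), points_table)
        assert res.total_points == 0
        assert res.stratum is Stratum.LOW

    def test_two_asserted_factors_add(self, points_table):
        pts = {f.id: f.points for f in points_table.factors}
        res = compute_risk_score(_inputs(sepsis=True, heart_failure=True), points_table)
        assert res.total_points == pts["sepsis"] + pts["heart_failure"]

    def test_missing_labs_reported_not_assessed(self, points_table):
        res = compute_risk_score(_inputs(), points_table)
        status = {c.factor_id: c.status for c in res.contributions}
        assert status["hypokalemia"] == "not assessed"
        assert status["baseline_qtc_ge_450"] == "not assessed"
        assert all(
            c.points_awarded == 0
            for c in res.contributions
            if c.status == "not assessed"
        )

    def test_total_equals_contribution_sum(self, points_table):
        res = compute_risk_score(
            _inputs(sex=Sex.female, age_years=80, qt_drug_count=2, sepsis=True),
            points_table,
        )
        assert res.total_points == sum(c.points_awarded for c in res.contributions)

    def test_exhaustive_enumeration_matches_oracle(self, points_table):
        """All combinations of the binary factors agree with the truth-table oracle."""
        toggles = {
            "age_years": (40, 70),
            "sex": (Sex.male, Sex.female),
            "on_loop_diuretic": (False, True),
            "serum_potassium_mmol_per_L": (4.2, 3.0),
            "baseline_qtc_ms": (420, 460),
            "acute_mi": (False, True),
            "sepsis": (False, True),
            "heart_failure": (False, True),
        }
        keys = list(toggles)
        for bits in itertools.product((0, 1), repeat=len(keys)):
            for qt_count in (0, 1, 2):
                x = _inputs(
                    qt_drug_count=qt_count,
                    **{k: toggles[k][b] for k, b in zip(keys, bits)},
                )
                res = compute_risk_score(x, points_table)
                assert res.total_points == oracle_points(x, points_table)

    @settings(derandomize=True, max_examples=300)
    @given(
        age=st.floats(0, 149),
        female=st.booleans(),
        k=st.one_of(st.none(), st.floats(2.0, 6.0)),
        diuretic=st.booleans(),
        mi=st.booleans(),
        sepsis=st.booleans(),
        hf=st.booleans(),
        qtc=st.one_of(st.none(), st.floats(300, 600)),
        nqt=st.integers(0, 5),
    )
    def test_randomised_inputs_match_oracle(
        self, points_table, age, female, k, diuretic, mi, sepsis, hf, qtc, nqt
    ):
        x = _inputs(
            age_years=age,
            sex=Sex.female if female else Sex.male,
            serum_potassium_mmol_per_L=k,
            on_loop_diuretic=diuretic,
            acute_mi=mi,
            sepsis=sepsis,
            heart_failure=hf,
            baseline_qtc_ms=qtc,
            qt_drug_count=nqt,
        )
        assert compute_risk_score(x, points_table).total_points == oracle_points(
            x, points_table
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        points=st.lists(st.integers(0, 5), min_size=10, max_size=10),
        flags=st.lists(st.booleans(), min_size=4, max_size=4),
    )
    def test_additivity_holds_for_arbitrary_tables(self, points, flags):
        ids = [
            "age_ge_68", "female_sex", "loop_diuretic", "hypokalemia",
            "baseline_qtc_ge_450", "acute_mi", "sepsis", "heart_failure",
            "one_qt_drug", "additional_qt_drugs",
        ]
        table = PointsTable(
            factors=tuple(
                PointsFactor(id=i, description=i, points=p) for i, p in zip(ids, points)
            )
        )
        diuretic, mi, sep, hf = flags
        x = _inputs(on_loop_diuretic=diuretic, acute_mi=mi, sepsis=sep, heart_failure=hf)
        assert compute_risk_score(x, table).total_points == oracle_points(x, table)

    def test_adding_a_factor_never_lowers_score(self, points_table):
        base = _inputs(sepsis=True)
        more = _inputs(sepsis=True, heart_failure=True)
        r0, r1 = (compute_risk_score(x, points_table) for x in (base, more))
        assert r1.total_points >= r0.total_points
        assert not (r0.stratum is Stratum.ELEVATED and r1.stratum is Stratum.LOW)

    def test_invalid_input_range_signals_entry_error(self):
        with pytest.raises(ValueError):
            _inputs(serum_potassium_mmol_per_L=0.5)
        with pytest.raises(ValueError):
            _inputs(age_years=200)


class TestStratify:
    @pytest.mark.parametrize(
        "points,expected",
        [(0, Stratum.LOW), (5, Stratum.LOW), (6, Stratum.LOW),
         (7, Stratum.ELEVATED), (12, Stratum.ELEVATED)],
    )
    def test_threshold_routing(self, points_table, points, expected):
        # the score-of-exactly-7 tie resolves to the baseline-ECG (ELEVATED) path
        assert stratify(points, points_table) is expected

    def test_monotone_in_points(self, points_table):
        strata = [stratify(p, points_table) for p in range(0, 20)]
        seen_elevated = False
        for s in strata:
            if s is Stratum.ELEVATED:
                seen_elevated = True
            assert not (seen_elevated and s is Stratum.LOW)


class TestAssessInteractions:
    def test_single_qt_drug_no_flags(self, catalog):
        res = assess_interactions([MedicationRecord(name="haloperidol")], catalog)
        assert not res.pharmacodynamic_stack_flag
        assert not res.pharmacokinetic_flag

    def test_two_known_risk_drugs_stack(self, catalog):
        res = assess_interactions(
            [MedicationRecord(name="haloperidol"), MedicationRecord(name="methadone")],
            catalog,
        )
        assert res.pharmacodynamic_stack_flag

    def test_inhibitor_sets_pk_flag_only(self, catalog):
        res = assess_interactions(
            [
                MedicationRecord(name="haloperidol"),
                MedicationRecord(name="fluvoxamine", is_metabolic_inhibitor=True),
            ],
            catalog,
        )
        assert res.pharmacokinetic_flag
        assert not res.pharmacodynamic_stack_flag  # fluvoxamine not in fixture

    def test_conditional_drug_counts_only_when_condition_asserted(self, catalog):
        meds = [MedicationRecord(name="haloperidol"), MedicationRecord(name="olanzapine")]
        assert not assess_interactions(meds, catalog, False).pharmacodynamic_stack_flag
        assert assess_interactions(meds, catalog, True).pharmacodynamic_stack_flag

    def test_route_and_dose_cautions_noted(self, catalog):
        res = assess_interactions(
            [
                MedicationRecord(
                    name="haloperidol", route="intravenous",
                    dose_text="supratherapeutic 20 mg",
                )
            ],
            catalog,
        )
        joined = " ".join(res.notes)
        assert "intravenous" in joined
        assert "supratherapeutic" in joined.lower()
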