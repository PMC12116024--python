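"""Tri-state evaluation, dose validity, rule firing and forecasting."""
import json
from datetime import date, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from immucast.engine import (
    EvalState,
    Recommendation,
    TriggerResult,
    TriState,
    assess_dose_validity,
    compute_age,
    eval_expr,
    evaluate_rule,
    forecast,
    next_due_date,
    t_and,
    t_not,
    t_or,
)
from immucast.errors import AsOfBeforeBirth, RuleNotExecutable
from immucast.logic import parse_logic
from immucast.patient_io import (
    Completeness,
    ConditionEntry,
    DoseEvent,
    DoseStatus,
    PatientRecord,
)
from immucast.rule_model import ActionType

AS_OF = date(2022, 7, 1)


def record(birth=date(2017, 7, 1), doses=(), conditions=(), allergies=(),
           completeness=Completeness.COMPLETE, id="t"):
    return PatientRecord(id=id, birth_date=birth, doses=tuple(doses),
                         conditions=tuple(conditions), allergies=tuple(allergies),
                         history_completeness=completeness)


def mmr_state(rb, rec, as_of=AS_OF, grace=4):
    return EvalState(rec, rb.category("mmr"), as_of, grace)


# --- age --------------------------------------------------------------------

def test_age_identity_case():
    age = compute_age(date(2020, 1, 1), date(2020, 1, 1))
    assert (age.days, age.whole_calendar_months, age.whole_years) == (0, 0, 0)


def test_age_clamped_anniversary():
    # born on Jan 31: the one-month anniversary clamps to Feb 29
    assert compute_age(date(2020, 1, 31), date(2020, 2, 29)).whole_calendar_months == 1
    assert compute_age(date(2020, 1, 31), date(2020, 2, 28)).whole_calendar_months == 0


def test_age_day_before_birthday():
    assert compute_age(date(2010, 5, 10), date(2022, 5, 9)).whole_years == 11
    assert compute_age(date(2010, 5, 10), date(2022, 5, 10)).whole_years == 12


def test_age_unknown_when_birth_missing():
    assert compute_age(None, AS_OF).known is False


def test_age_rejects_as_of_before_birth():
    with pytest.raises(AsOfBeforeBirth):
        compute_age(date(2022, 7, 2), AS_OF)


# --- Kleene algebra ---------------------------------------------------------

T, F, U = TriState.TRUE, TriState.FALSE, TriState.UNKNOWN


@pytest.mark.parametrize("a,b,conj,disj", [
    (T, T, T, T), (T, F, F, T), (T, U, U, T),
    (F, F, F, F), (F, U, F, U), (U, U, U, U),
])
def test_kleene_truth_tables(a, b, conj, disj):
    assert t_and([a, b]) is conj and t_and([b, a]) is conj
    assert t_or([a, b]) is disj and t_or([b, a]) is disj


def test_kleene_negation():
    assert t_not(T) is F and t_not(F) is T and t_not(U) is U


tri = st.sampled_from([T, F, U])


@given(st.lists(tri, min_size=2, max_size=5))
@settings(max_examples=100, deadline=None)
def test_de_morgan_and_involution(vals):
    assert t_not(t_and(vals)) is t_or([t_not(v) for v in vals])
    assert t_not(t_not(vals[0])) is vals[0]
    # absorption: a AND (a OR b) == a ; a OR (a AND b) == a
    a, b = vals[0], vals[1]
    assert t_and([a, t_or([a, b])]) is a
    assert t_or([a, t_and([a, b])]) is a


# --- predicate evaluation ---------------------------------------------------

def test_age_ge_true_on_anniversary_day(rb):
    state = mmr_state(rb, record(birth=date(2021, 7, 1)))  # exactly 12 months
    assert eval_expr(parse_logic("AGE_GE[12 mo]"), state) is T
    assert eval_expr(parse_logic("AGE_GT[12 mo]"), state) is F  # GT excludes equality
    assert eval_expr(parse_logic("AGE_LT[12 mo]"), state) is F


def test_age_unknown_propagates(rb):
    state = mmr_state(rb, record(birth=None))
    for text in ("AGE_GE[12 mo]", "AGE_GT[18 y]", "AGE_LT[1 d]"):
        assert eval_expr(parse_logic(text), state) is U


def test_dose_count_under_incomplete_history(rb):
    rec = record(completeness=Completeness.INCOMPLETE)
    state = mmr_state(rb, rec)
    assert eval_expr(parse_logic("DOSE_COUNT_EQ[0]"), state) is U
    assert eval_expr(parse_logic("DOSE_COUNT_GE[1]"), state) is U
    rec2 = record(doses=[DoseEvent("03", date(2018, 8, 1))],
                  completeness=Completeness.INCOMPLETE)
    # one valid dose on record: >=1 is certain even if more doses exist
    assert eval_expr(parse_logic("DOSE_COUNT_GE[1]"), mmr_state(rb, rec2)) is T
    assert eval_expr(parse_logic("DOSE_COUNT_EQ[1]"), mmr_state(rb, rec2)) is U


def test_condition_absence_depends_on_completeness(rb):
    present = parse_logic("CONDITION_PRESENT[PREGNANCY]")
    assert eval_expr(present, mmr_state(rb, record())) is F
    assert eval_expr(present, mmr_state(
        rb, record(completeness=Completeness.UNKNOWN))) is U
    assert eval_expr(present, mmr_state(
        rb, record(conditions=[ConditionEntry("PREGNANCY")]))) is T


def test_season_window_wraps_year_end(rb):
    expr = parse_logic("SEASON_WINDOW[10-01, 03-31]")
    assert eval_expr(expr, mmr_state(rb, record(), as_of=date(2022, 12, 15))) is T
    assert eval_expr(expr, mmr_state(rb, record(), as_of=date(2022, 7, 1))) is F


# --- dose validity ----------------------------------------------------------

def test_dose_at_exact_minimum_age_is_valid(rb):
    rec = record(birth=date(2021, 7, 1), doses=[DoseEvent("03", date(2022, 7, 1))])
    (a,) = assess_dose_validity(rec, rb.category("mmr"), grace_days=4)
    assert a.valid is T and a.series_position == 1


def test_dose_below_minimum_age_is_invalid(rb):
    rec = record(birth=date(2021, 7, 1), doses=[DoseEvent("03", date(2022, 6, 1))])
    (a,) = assess_dose_validity(rec, rb.category("mmr"), grace_days=4)
    assert a.valid is F and "below-minimum-age" in a.reasons


def test_grace_period_rescues_slightly_early_dose(rb):
    rec = record(birth=date(2021, 7, 1), doses=[DoseEvent("03", date(2022, 6, 28))])
    (with_grace,) = assess_dose_validity(rec, rb.category("mmr"), grace_days=4)
    (without,) = assess_dose_validity(rec, rb.category("mmr"), grace_days=0)
    assert with_grace.valid is T and without.valid is F


def test_short_interval_second_dose_invalid(rb):
    rec = record(birth=date(2016, 7, 1),
                 doses=[DoseEvent("03", date(2017, 8, 1)),
                        DoseEvent("03", date(2017, 8, 21))])  # 20 days later
    a1, a2 = assess_dose_validity(rec, rb.category("mmr"), grace_days=0)
    assert a1.valid is T
    assert a2.valid is F and "below-minimum-interval" in a2.reasons


def test_not_done_dose_never_valid(rb):
    rec = record(birth=date(2016, 7, 1),
                 doses=[DoseEvent("03", date(2017, 8, 1), DoseStatus.NOT_DONE)])
    (a,) = assess_dose_validity(rec, rb.category("mmr"))
    assert a.valid is F and "not-done" in a.reasons


def test_same_day_duplicates_count_once(rb):
    rec = record(birth=date(2016, 7, 1),
                 doses=[DoseEvent("03", date(2017, 8, 1)),
                        DoseEvent("94", date(2017, 8, 1))])
    a1, a2 = assess_dose_validity(rec, rb.category("mmr"))
    assert a1.valid is F and "duplicate-same-day" in a1.reasons
    assert a2.valid is T and a2.series_position == 1


# --- rule firing ------------------------------------------------------------

def test_mmr_dose1_rule_trace(rb):
    rule = rb.rule("MMR-R01")
    fired = evaluate_rule(rule, mmr_state(rb, record(birth=date(2021, 6, 1))))
    assert fired is TriggerResult.FIRED  # 13 months old, no doses
    not_fired = evaluate_rule(rule, mmr_state(rb, record(birth=date(2021, 9, 1))))
    assert not_fired is TriggerResult.NOT_FIRED  # 10 months old
    indet = evaluate_rule(rule, mmr_state(rb, record(birth=None)))
    assert indet is TriggerResult.INDETERMINATE  # unknown birth date


def test_non_executable_rule_raises(rb):
    rule = rb.rule("DTAP-R01")
    with pytest.raises(RuleNotExecutable):
        evaluate_rule(rule, mmr_state(rb, record()))


# --- forecasting ------------------------------------------------------------

def mmr_rec(recs):
    return next(r for r in recs if r.vaccine_category == "mmr")


def test_forecast_thirteen_month_old_due_now(rb):
    rec = record(birth=date(2021, 6, 1))
    out = mmr_rec(forecast(rec, rb, AS_OF))
    assert out.action is ActionType.RECOMMEND_DOSE
    assert out.dose_number == 1
    assert out.earliest_date == date(2022, 6, 1)  # 12-month anniversary
    assert out.fired_rule_ids


def test_forecast_component_allergy_contraindicated(rb):
    rec = record(birth=date(2021, 6, 1),
                 allergies=[ConditionEntry("ANAPHYLAXIS-NEOMYCIN")])
    out = mmr_rec(forecast(rec, rb, AS_OF))
    assert out.action is ActionType.CONTRAINDICATED
    assert out.earliest_date is None and out.recommended_date is None


def test_forecast_two_valid_doses_complete(rb):
    rec = record(birth=date(2015, 1, 15),
                 doses=[DoseEvent("03", date(2016, 1, 20)),
                        DoseEvent("03", date(2019, 5, 1))])
    assert mmr_rec(forecast(rec, rb, AS_OF)).action is ActionType.SERIES_COMPLETE


def test_forecast_unknown_birth_is_insufficient_data(rb):
    out = forecast(record(birth=None), rb, AS_OF)
    assert all(r.action is ActionType.INSUFFICIENT_DATA for r in out)
    assert out  # explicit output, not a silent skip


def test_routine_child_gets_no_dengue_output(rb):
    out = forecast(record(birth=date(2021, 6, 1)), rb, AS_OF)
    assert [r.vaccine_category for r in out] == ["mmr"]


def test_eligible_dengue_patient(rb):
    rec = record(
        birth=date(2012, 7, 1),
        conditions=[ConditionEntry("DENGUE-PREVIOUS-INFECTION-LAB-CONFIRMED"),
                    ConditionEntry("RESIDENCE-DENGUE-ENDEMIC-AREA")],
    )
    den = next(r for r in forecast(rec, rb, AS_OF) if r.vaccine_category == "dengue")
    assert den.action is ActionType.RECOMMEND_DOSE and den.dose_number == 1


def test_precaution_noted_alongside_recommendation(rb):
    rec = record(birth=date(2021, 6, 1),
                 conditions=[ConditionEntry("MODERATE-SEVERE-ACUTE-ILLNESS")])
    out = mmr_rec(forecast(rec, rb, AS_OF))
    assert out.action is ActionType.RECOMMEND_DOSE
    assert "precaution" in out.status_note


# --- next due date ----------------------------------------------------------

def test_next_due_first_dose_at_first_birthday(rb):
    rec = record(birth=date(2021, 1, 15), doses=[])
    assert next_due_date(rec, rb.category("mmr"), rb) == date(2022, 1, 15)


def test_next_due_second_dose_after_28_days(rb):
    rec = record(birth=date(2021, 1, 15), doses=[DoseEvent("03", date(2022, 1, 15))])
    assert next_due_date(rec, rb.category("mmr"), rb) == date(2022, 2, 12)


def test_next_due_none_when_complete(rb):
    rec = record(birth=date(2015, 1, 15),
                 doses=[DoseEvent("03", date(2016, 1, 20)),
                        DoseEvent("03", date(2019, 5, 1))])
    assert next_due_date(rec, rb.category("mmr"), rb) is None


# --- engine-wide properties -------------------------------------------------

hist_dates = st.dates(min_value=date(2005, 1, 1), max_value=date(2022, 6, 30))
random_records = st.builds(
    record,
    birth=st.one_of(st.none(), st.dates(min_value=date(2004, 7, 2),
                                        max_value=date(2022, 7, 1))),
    doses=st.lists(st.builds(DoseEvent, vaccine_code=st.sampled_from(["03", "94"]),
                             date=hist_dates), max_size=4),
    conditions=st.lists(st.builds(ConditionEntry, code=st.sampled_from(
        ["PREGNANCY", "SEVERE-IMMUNODEFICIENCY", "MODERATE-SEVERE-ACUTE-ILLNESS",
         "EVIDENCE-OF-IMMUNITY-MMR", "INTERNATIONAL-TRAVEL"])), max_size=2),
    completeness=st.sampled_from(list(Completeness)),
)


@given(random_records)
@settings(max_examples=150, deadline=None)
def test_contraindication_dominance(rb, rec):
    """No category's output ever mixes CONTRAINDICATED with a dose push."""
    recs = forecast(rec, rb, AS_OF)
    by_cat = {}
    for r in recs:
        by_cat.setdefault(r.vaccine_category, []).append(r.action)
    for actions in by_cat.values():
        if ActionType.CONTRAINDICATED in actions:
            assert ActionType.RECOMMEND_DOSE not in actions
            assert len(actions) == 1


@given(random_records, st.integers(min_value=0, max_value=1500))
@settings(max_examples=100, deadline=None)
def test_monotone_series_progress(rb, rec, advance):
    """Advancing as-of never reduces valid doses or un-completes a series."""
    if rec.birth_date is None:
        return
    later = AS_OF + timedelta(days=advance)
    cat = rb.category("mmr")
    count = sum(1 for a in assess_dose_validity(rec, cat) if a.valid is T)
    count_later = sum(1 for a in assess_dose_validity(rec, cat) if a.valid is T)
    assert count_later >= count
    if mmr_rec_or_none(forecast(rec, rb, AS_OF)) == ActionType.SERIES_COMPLETE:
        assert mmr_rec_or_none(forecast(rec, rb, later)) == ActionType.SERIES_COMPLETE


def mmr_rec_or_none(recs):
    for r in recs:
        if r.vaccine_category == "mmr":
            return r.action
    return None


@given(random_records)
@settings(max_examples=75, deadline=None)
def test_forecast_is_deterministic(rb, rec):
    a = json.dumps([r.to_dict() for r in forecast(rec, rb, AS_OF)], sort_keys=True)
    b = json.dumps([r.to_dict() for r in forecast(rec, rb, AS_OF)], sort_keys=True)
    assert a == b


def test_recommendation_invariants_hold_structurally(rb):
    rec = Recommendation("mmr", ActionType.CONTRAINDICATED)
    assert rec.earliest_date is None and rec.recommended_date is None
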