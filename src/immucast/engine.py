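"""Unknown-aware rule evaluation and immunization forecasting.

Evaluation is three-valued (Kleene strong logic): a predicate over data the
record does not contain evaluates to UNKNOWN rather than FALSE, because the
absence of evidence in an incomplete record is not evidence of absence.
UNKNOWN propagates through AND/OR/NOT by Kleene's tables and surfaces as an
explicit INSUFFICIENT_DATA recommendation, never as a silent skip.

Dose validity (whether an administered dose counts toward its series) is
computed at evaluation time from the recorded dates and the category's
series parameters — minimum age and minimum interval, each relaxed by the
configurable grace period — not from a precomputed lookup table.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from typing import List, Optional, Sequence, Tuple

from .errors import (
    AsOfBeforeBirth,
    RuleNotExecutable,
    UnsupportedPredicateKind,
)
from .logic import And, Atom, AtomicPredicate, Comparator, Expr, Not, Or, PredicateKind
from .patient_io import Completeness, DoseEvent, DoseStatus, PatientRecord
from .quantities import Duration, Unit, add_duration, whole_elapsed
from .rule_model import ActionType, Rule, Rulebase, RuleClass, VaccineCategory
from . import valuesets

#: default grace period (days) subtracted from minimum ages and minimum
#: intervals when judging dose validity; standard ACIP practice, overridable.
DEFAULT_GRACE_DAYS = 4


class TriState(Enum):
    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"


def t_not(a: TriState) -> TriState:
    if a is TriState.TRUE:
        return TriState.FALSE
    if a is TriState.FALSE:
        return TriState.TRUE
    return TriState.UNKNOWN


def t_and(values: Sequence[TriState]) -> TriState:
    if any(v is TriState.FALSE for v in values):
        return TriState.FALSE
    if any(v is TriState.UNKNOWN for v in values):
        return TriState.UNKNOWN
    return TriState.TRUE


def t_or(values: Sequence[TriState]) -> TriState:
    if any(v is TriState.TRUE for v in values):
        return TriState.TRUE
    if any(v is TriState.UNKNOWN for v in values):
        return TriState.UNKNOWN
    return TriState.FALSE


def t_bool(b: bool) -> TriState:
    return TriState.TRUE if b else TriState.FALSE


class TriggerResult(Enum):
    FIRED = "FIRED"
    NOT_FIRED = "NOT_FIRED"
    INDETERMINATE = "INDETERMINATE"


# --- age --------------------------------------------------------------------

@dataclass(frozen=True)
class Age:
    """Patient age at a reference date, in whole units.

    Calendar-month and year components count same-day-of-month anniversaries
    with end-of-month clamping (born Jan 31: the 1-month anniversary is the
    last day of February).
    """

    known: bool
    days: Optional[int] = None
    whole_calendar_months: Optional[int] = None
    whole_years: Optional[int] = None

    UNKNOWN = None  # set below


Age.UNKNOWN = Age(known=False)


def compute_age(birth_date: Optional[date], as_of: date) -> Age:
    if birth_date is None:
        return Age.UNKNOWN
    if as_of < birth_date:
        raise AsOfBeforeBirth(f"as-of {as_of} precedes birth {birth_date}")
    months = whole_elapsed(birth_date, as_of, Unit.MONTHS)
    return Age(
        known=True,
        days=(as_of - birth_date).days,
        whole_calendar_months=months,
        whole_years=months // 12,
    )


def _age_in_unit(age: Age, unit: Unit) -> int:
    if unit is Unit.DAYS:
        return age.days
    if unit is Unit.WEEKS:
        return age.days // 7
    if unit is Unit.MONTHS:
        return age.whole_calendar_months
    if unit is Unit.YEARS:
        return age.whole_years
    raise ValueError(unit)


_CMP = {
    Comparator.GE: lambda a, b: a >= b,
    Comparator.GT: lambda a, b: a > b,
    Comparator.LE: lambda a, b: a <= b,
    Comparator.LT: lambda a, b: a < b,
    Comparator.EQ: lambda a, b: a == b,
}


# --- dose validity ----------------------------------------------------------

@dataclass(frozen=True)
class ValidityAssessment:
    dose: DoseEvent
    valid: TriState
    reasons: Tuple[str, ...] = ()
    series_position: Optional[int] = None  # 1-based, only for valid doses


def _shifted_min(anchor: date, minimum: Duration, grace_days: int) -> date:
    return add_duration(anchor, minimum) - timedelta(days=grace_days)


def assess_dose_validity(
    record: PatientRecord,
    category: VaccineCategory,
    grace_days: int = DEFAULT_GRACE_DAYS,
    cvx_codes=None,
) -> List[ValidityAssessment]:
    """Judge every recorded dose of ``category`` against the series rules.

    A COMPLETED dose is valid iff it was administered no earlier than
    (minimum age - grace) and (minimum interval from the previous valid dose
    - grace).  NOT_DONE / ENTERED_IN_ERROR doses are never valid.  Same-day
    duplicates count once (the later record; earlier ones are flagged).
    Doses beyond the series size do not count.
    """
    if category.series is None:
        raise ValueError(f"category {category.slug!r} has no series parameters")
    codes = cvx_codes if cvx_codes is not None else valuesets.category_cvx()[category.slug]
    series = category.series
    out: List[ValidityAssessment] = []
    position = 1
    prev_valid_date: Optional[date] = None
    cat_doses = [d for d in record.doses if d.vaccine_code in codes]
    for idx, dose in enumerate(cat_doses):
        if dose.status is not DoseStatus.COMPLETED:
            out.append(ValidityAssessment(dose, TriState.FALSE, (dose.status.value,)))
            continue
        later_same_day = any(
            d.status is DoseStatus.COMPLETED and d.date == dose.date
            for d in cat_doses[idx + 1:]
        )
        if later_same_day:  # count once, keep the latest record
            out.append(ValidityAssessment(dose, TriState.FALSE, ("duplicate-same-day",)))
            continue
        if position > series.size:
            out.append(ValidityAssessment(dose, TriState.FALSE, ("beyond-series-size",)))
            continue
        spec = series.doses[position - 1]
        reasons: List[str] = []
        unknown = False
        if spec.min_age is not None:
            if record.birth_date is None:
                unknown = True
            elif dose.date < _shifted_min(record.birth_date, spec.min_age, grace_days):
                reasons.append("below-minimum-age")
        if spec.min_interval is not None and prev_valid_date is not None:
            if dose.date < _shifted_min(prev_valid_date, spec.min_interval, grace_days):
                reasons.append("below-minimum-interval")
        if reasons:
            out.append(ValidityAssessment(dose, TriState.FALSE, tuple(reasons)))
        elif unknown:
            out.append(ValidityAssessment(dose, TriState.UNKNOWN, ("unknown-birth-date",)))
        else:
            out.append(ValidityAssessment(dose, TriState.TRUE, (), position))
            prev_valid_date = dose.date
            position += 1
    return out


# --- evaluation state -------------------------------------------------------

@dataclass
class EvalState:
    """Per-(record, category, as_of) context for predicate evaluation."""

    record: PatientRecord
    category: VaccineCategory
    as_of: date
    grace_days: int = DEFAULT_GRACE_DAYS
    age: Age = field(init=False)
    assessments: List[ValidityAssessment] = field(init=False)

    def __post_init__(self):
        self.age = compute_age(self.record.birth_date, self.as_of)
        self.assessments = assess_dose_validity(
            self.record, self.category, self.grace_days
        )

    # interval [lo, hi] of possible valid-dose counts: UNKNOWN-valid doses and
    # incompletely recorded histories widen the upper bound.
    def valid_count_range(self) -> Tuple[int, float]:
        lo = sum(1 for a in self.assessments if a.valid is TriState.TRUE)
        hi: float = lo + sum(1 for a in self.assessments if a.valid is TriState.UNKNOWN)
        if self.record.history_completeness is not Completeness.COMPLETE:
            hi = math.inf
        return lo, hi

    def valid_doses(self) -> List[ValidityAssessment]:
        return [a for a in self.assessments if a.valid is TriState.TRUE]

    def completed_category_doses(self) -> List[DoseEvent]:
        return [a.dose for a in self.assessments if a.dose.status is DoseStatus.COMPLETED]


def _condition_lookup(state: EvalState, code: str) -> TriState:
    from .patient_io import ClinicalStatus

    entries = list(state.record.conditions) + list(state.record.allergies)
    saw_unknown_status = False
    for e in entries:
        if e.code == code:
            if e.clinical_status is ClinicalStatus.ACTIVE:
                return TriState.TRUE
            if e.clinical_status is ClinicalStatus.UNKNOWN:
                saw_unknown_status = True
            # RESOLVED entries do not assert present
    if saw_unknown_status:
        return TriState.UNKNOWN
    if state.record.history_completeness is Completeness.COMPLETE:
        return TriState.FALSE
    return TriState.UNKNOWN  # absence of evidence is not evidence of absence


def eval_predicate(p: AtomicPredicate, state: EvalState) -> TriState:
    kind = p.kind
    if kind is PredicateKind.AGE_CMP:
        if not state.age.known:
            return TriState.UNKNOWN
        return t_bool(_CMP[p.comparator](_age_in_unit(state.age, p.threshold.unit),
                                         p.threshold.value))
    if kind is PredicateKind.DOSE_COUNT_CMP:
        # the set of possible valid-dose counts is the interval [lo, hi]
        # (hi is inf when the history may be incomplete); the predicate is
        # TRUE/FALSE only if it holds for all/no counts in that interval.
        lo, hi = state.valid_count_range()
        k = p.count
        c = p.comparator
        if c is Comparator.GE:
            all_sat, none_sat = lo >= k, hi < k
        elif c is Comparator.GT:
            all_sat, none_sat = lo > k, hi <= k
        elif c is Comparator.LE:
            all_sat, none_sat = hi <= k, lo > k
        elif c is Comparator.LT:
            all_sat, none_sat = hi < k, lo >= k
        else:  # EQ
            all_sat, none_sat = lo == hi == k, k < lo or k > hi
        if all_sat:
            return TriState.TRUE
        if none_sat:
            return TriState.FALSE
        return TriState.UNKNOWN
    if kind is PredicateKind.INTERVAL_SINCE_DOSE_CMP:
        doses = state.completed_category_doses()
        if len(doses) < p.reference_dose:
            # an interval from a dose never recorded satisfies no bound
            return TriState.FALSE
        ref = doses[p.reference_dose - 1]
        elapsed = whole_elapsed(ref.date, state.as_of, p.threshold.unit)
        return t_bool(_CMP[p.comparator](elapsed, p.threshold.value))
    if kind is PredicateKind.CONDITION_PRESENT:
        return _condition_lookup(state, p.code)
    if kind is PredicateKind.CONDITION_ABSENT:
        return t_not(_condition_lookup(state, p.code))
    if kind is PredicateKind.PRIOR_DOSE_VALID:
        doses = state.assessments
        if len(doses) < p.reference_dose:
            return TriState.FALSE  # a dose never given is not a valid dose
        return doses[p.reference_dose - 1].valid
    if kind is PredicateKind.SEASON_WINDOW:
        start, end = p.season
        mmdd = f"{state.as_of.month:02d}-{state.as_of.day:02d}"
        if start <= end:
            return t_bool(start <= mmdd <= end)
        return t_bool(mmdd >= start or mmdd <= end)  # wraps the year end
    raise UnsupportedPredicateKind(str(kind))


def eval_expr(e: Expr, state: EvalState) -> TriState:
    if isinstance(e, Atom):
        return eval_predicate(e.pred, state)
    if isinstance(e, Not):
        return t_not(eval_expr(e.child, state))
    if isinstance(e, And):
        return t_and([eval_expr(c, state) for c in e.children])
    if isinstance(e, Or):
        return t_or([eval_expr(c, state) for c in e.children])
    raise TypeError(type(e))


def evaluate_rule(rule: Rule, state: EvalState) -> TriggerResult:
    if not rule.executable or rule.logic is None:
        raise RuleNotExecutable(rule.id)
    v = eval_expr(rule.logic, state)
    if v is TriState.TRUE:
        return TriggerResult.FIRED
    if v is TriState.FALSE:
        return TriggerResult.NOT_FIRED
    return TriggerResult.INDETERMINATE


# --- recommendations --------------------------------------------------------

@dataclass(frozen=True)
class Recommendation:
    vaccine_category: str  # category slug
    action: ActionType
    dose_number: Optional[int] = None
    earliest_date: Optional[date] = None
    recommended_date: Optional[date] = None
    fired_rule_ids: Tuple[str, ...] = ()
    status_note: str = ""

    def to_dict(self) -> dict:
        return {
            "vaccine_category": self.vaccine_category,
            "action": self.action.value,
            "dose_number": self.dose_number,
            "earliest_date": self.earliest_date.isoformat() if self.earliest_date else None,
            "recommended_date": self.recommended_date.isoformat() if self.recommended_date else None,
            "fired_rule_ids": list(self.fired_rule_ids),
            "status_note": self.status_note,
        }


def next_due_date(
    record: PatientRecord,
    category: VaccineCategory,
    rb: Rulebase,
    grace_days: int = DEFAULT_GRACE_DAYS,
) -> Optional[date]:
    """Earliest valid date for the next outstanding dose, or None if the
    series is complete.  Computed at call time from recorded dates and the
    series parameters (no precomputed interval table); the grace period is a
    retrospective validity tolerance and does not advance due dates."""
    if category.series is None:
        return None
    assessments = assess_dose_validity(record, category, grace_days)
    valid = [a for a in assessments if a.valid is TriState.TRUE]
    n_next = len(valid) + 1
    if n_next > category.series.size:
        return None
    spec = category.series.doses[n_next - 1]
    bounds: List[date] = []
    if spec.min_age is not None and record.birth_date is not None:
        bounds.append(add_duration(record.birth_date, spec.min_age))
    if spec.min_interval is not None and valid:
        bounds.append(add_duration(valid[-1].dose.date, spec.min_interval))
    return max(bounds) if bounds else None


def _timing_date(state: EvalState, offset) -> Optional[date]:
    if offset is None:
        return None
    if offset.anchor == "birth":
        if state.record.birth_date is None:
            return None
        return add_duration(state.record.birth_date, offset.offset)
    if offset.anchor == "prev_dose":
        valid = state.valid_doses()
        if not valid:
            return None
        return add_duration(valid[-1].dose.date, offset.offset)
    # dose<k>: k-th administered completed dose
    k = int(offset.anchor[4:])
    doses = state.completed_category_doses()
    if len(doses) < k:
        return None
    return add_duration(doses[k - 1].date, offset.offset)


def forecast(
    record: PatientRecord,
    rb: Rulebase,
    as_of: date,
    grace_days: int = DEFAULT_GRACE_DAYS,
) -> List[Recommendation]:
    """Evaluate every executable category and emit one recommendation each.

    Conflict resolution, in priority order: a FIRED contraindication rule
    suppresses everything else for the category; a complete series reports
    SERIES_COMPLETE; otherwise the lowest-numbered outstanding recommended
    dose wins (ties broken by rule id); then scheduled follow-ups and bare
    precautions; if nothing fired but some rule was INDETERMINATE the output
    is an explicit INSUFFICIENT_DATA.  Categories where every rule is
    determinately inapplicable produce no recommendation.
    """
    recs: List[Recommendation] = []
    for category in sorted(rb.categories, key=lambda c: c.name):
        if not category.executable:
            continue
        state = EvalState(record, category, as_of, grace_days)
        rules = [r for r in rb.rules_for(category.slug) if r.executable]
        results = {r.id: evaluate_rule(r, state) for r in rules}
        by_id = {r.id: r for r in rules}
        fired = sorted(rid for rid, res in results.items() if res is TriggerResult.FIRED)
        indeterminate = sorted(
            rid for rid, res in results.items() if res is TriggerResult.INDETERMINATE
        )

        def fired_of(action_type, rule_class=None):
            return [
                rid for rid in fired
                if by_id[rid].action.type is action_type
                and (rule_class is None or by_id[rid].rule_class is rule_class)
            ]

        contra = fired_of(ActionType.CONTRAINDICATED, RuleClass.CONTRA_PRECAUTION)
        precaution = fired_of(ActionType.PRECAUTION)
        complete = fired_of(ActionType.SERIES_COMPLETE)
        recommend = fired_of(ActionType.RECOMMEND_DOSE)
        followup = fired_of(ActionType.SCHEDULE_FOLLOWUP)

        lo_valid = sum(1 for a in state.assessments if a.valid is TriState.TRUE)
        series_done = category.series is not None and lo_valid >= category.series.size

        if contra:
            recs.append(Recommendation(
                category.slug, ActionType.CONTRAINDICATED,
                fired_rule_ids=tuple(contra),
                status_note="; ".join(by_id[r].description for r in contra),
            ))
            continue
        if complete or series_done:
            recs.append(Recommendation(
                category.slug, ActionType.SERIES_COMPLETE,
                fired_rule_ids=tuple(complete) or tuple(recommend) or tuple(fired),
                status_note="series complete",
            ))
            continue
        note_bits = []
        if precaution:
            note_bits.append(
                "precaution: " + "; ".join(by_id[r].description for r in precaution)
            )
        if recommend:
            chosen_id = min(recommend, key=lambda rid: (by_id[rid].action.dose_number, rid))
            chosen = by_id[chosen_id]
            due = next_due_date(record, category, rb, grace_days)
            rec_date = _timing_date(state, (chosen.action.timing or None) and chosen.action.timing.recommended)
            recs.append(Recommendation(
                category.slug, ActionType.RECOMMEND_DOSE,
                dose_number=chosen.action.dose_number,
                earliest_date=due,
                recommended_date=rec_date,
                fired_rule_ids=tuple(sorted(set(recommend) | set(precaution))),
                status_note="; ".join([chosen.description] + note_bits),
            ))
            continue
        if followup:
            chosen = by_id[followup[0]]
            t = chosen.action.timing
            earliest = _timing_date(state, t.earliest if t else None)
            rec_date = _timing_date(state, t.recommended if t else None)
            recs.append(Recommendation(
                category.slug, ActionType.SCHEDULE_FOLLOWUP,
                dose_number=chosen.action.dose_number,
                earliest_date=earliest,
                recommended_date=rec_date or earliest,
                fired_rule_ids=tuple(sorted(set(followup) | set(precaution))),
                status_note="; ".join([chosen.description] + note_bits),
            ))
            continue
        if precaution:
            recs.append(Recommendation(
                category.slug, ActionType.PRECAUTION,
                fired_rule_ids=tuple(precaution),
                status_note="; ".join(by_id[r].description for r in precaution),
            ))
            continue
        if indeterminate:
            recs.append(Recommendation(
                category.slug, ActionType.INSUFFICIENT_DATA,
                status_note="indeterminate rules: " + ", ".join(indeterminate),
            ))
        # all rules determinately inapplicable: no recommendation
    recs.sort(key=lambda r: (r.vaccine_category, r.dose_number or 0))
    return recs
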