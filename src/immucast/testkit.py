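"""Per-rule positive/negative test-case generation and a test runner.

Every executable rule gets one positive case whose fixture satisfies each
atomic predicate at its boundary (a >=12-month age predicate is exercised on
the 12-month anniversary day; a >=28-day interval at exactly 28 days), and
one negative case per atomic predicate, built by perturbing only that
predicate minimally: age one day below a >= threshold, an interval one day
short, a condition code removed.  Perturbing a NOT(PRIOR_DOSE_VALID[n])
literal moves dose n to a valid date, which is the minimal change to the
*record* even though a dose-count predicate may flip with it.

The runner serializes every fixture to a FHIR R4 bundle and reads it back
before evaluating, so patient I/O is exercised on 100% of executed cases.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from typing import Dict, List, Optional, Tuple

from .engine import (
    DEFAULT_GRACE_DAYS,
    EvalState,
    TriggerResult,
    TriState,
    evaluate_rule,
)
from .errors import UnknownRuleId, UnsatisfiableRule
from .logic import Comparator, PredicateKind, conjunctive_literals
from .patient_io import (
    Completeness,
    ConditionEntry,
    DoseEvent,
    PatientRecord,
    bundle_json,
    read_fhir_bundle,
)
from .quantities import Duration, Unit, add_duration, whole_elapsed
from .rule_model import Rule, Rulebase

#: fixed evaluation date for generated fixtures (any date works; one date
#: keeps fixtures reproducible and diffable)
FIXTURE_AS_OF = date(2022, 7, 1)


class Polarity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class TestCase:
    __test__ = False  # keep pytest from collecting this domain class

    rule_id: str
    polarity: Polarity
    fixture: PatientRecord
    as_of: date
    expected: TriggerResult
    perturbed_predicate: Optional[Tuple[int, ...]] = None  # path into the logic tree


class RuleStatus(str, Enum):
    PASSED = "PASSED"
    FAILED = "FAILED"
    PENDING = "PENDING"


@dataclass(frozen=True)
class CaseOutcome:
    rule_id: str
    polarity: Polarity
    expected: TriggerResult
    actual: TriggerResult
    passed: bool


@dataclass
class TestReport:
    statuses: Dict[str, RuleStatus] = field(default_factory=dict)
    outcomes: List[CaseOutcome] = field(default_factory=list)

    @property
    def summary(self) -> Dict[str, int]:
        return {
            "rules_passed": sum(1 for s in self.statuses.values() if s is RuleStatus.PASSED),
            "rules_failed": sum(1 for s in self.statuses.values() if s is RuleStatus.FAILED),
            "rules_pending": sum(1 for s in self.statuses.values() if s is RuleStatus.PENDING),
            "cases_run": len(self.outcomes),
            "cases_passed": sum(1 for o in self.outcomes if o.passed),
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "summary": self.summary,
                "rules": {rid: s.value for rid, s in sorted(self.statuses.items())},
                "cases": [
                    {
                        "rule_id": o.rule_id,
                        "polarity": o.polarity.value,
                        "expected": o.expected.value,
                        "actual": o.actual.value,
                        "passed": o.passed,
                    }
                    for o in self.outcomes
                ],
            },
            indent=2,
        )

    def render_text(self, color: bool = False) -> str:
        """Status words, optionally ANSI-colored (green passed / red failed /
        yellow pending), echoing the chart-tracking color convention."""
        paint = {
            RuleStatus.PASSED: "\x1b[32m{}\x1b[0m",
            RuleStatus.FAILED: "\x1b[31m{}\x1b[0m",
            RuleStatus.PENDING: "\x1b[33m{}\x1b[0m",
        }
        lines = []
        for rid in sorted(self.statuses):
            word = self.statuses[rid].value
            if color:
                word = paint[self.statuses[rid]].format(word)
            lines.append(f"{rid:<12} {word}")
        s = self.summary
        lines.append(
            f"passed {s['rules_passed']}  failed {s['rules_failed']}  "
            f"pending {s['rules_pending']}  ({s['cases_passed']}/{s['cases_run']} cases)"
        )
        return "\n".join(lines)


# --- fixture construction ---------------------------------------------------

def _back_shift(as_of: date, dur: Duration) -> date:
    """A date b with whole_elapsed(b, as_of, unit) == dur.value, at boundary."""
    if dur.unit is Unit.DAYS:
        return as_of - timedelta(days=dur.value)
    if dur.unit is Unit.WEEKS:
        return as_of - timedelta(days=7 * dur.value)
    months = dur.value if dur.unit is Unit.MONTHS else 12 * dur.value
    # latest b with whole_elapsed(b, as_of) == value: start safely early and
    # walk forward while the next day still satisfies the bound
    b = as_of - timedelta(days=31 * months + 62)
    while whole_elapsed(b + timedelta(days=1), as_of, dur.unit) >= dur.value:
        b += timedelta(days=1)
    return b


def _age_ok(birth: date, as_of: date, age_targets) -> bool:
    if birth > as_of:
        return False
    from .engine import compute_age, _age_in_unit, _CMP

    age = compute_age(birth, as_of)
    for pred, target in age_targets:
        got = _CMP[pred.comparator](_age_in_unit(age, pred.threshold.unit),
                                    pred.threshold.value)
        if got != target:
            return False
    return True


def _birth_candidates(as_of: date, age_targets, default_candidates) -> List[date]:
    """Birth dates satisfying the age targets, boundary candidates first."""
    candidates: List[date] = []
    for pred, target in age_targets:
        b0 = _back_shift(as_of, pred.threshold)
        one_more = _back_shift(
            as_of, Duration(pred.threshold.value + 1, pred.threshold.unit)
        )
        c, t = pred.comparator, target
        if (c, t) in ((Comparator.GE, True), (Comparator.LE, True), (Comparator.EQ, True),
                      (Comparator.GT, False), (Comparator.LT, False)):
            candidates += [b0]
        if (c, t) in ((Comparator.GE, False), (Comparator.LT, True), (Comparator.EQ, False)):
            candidates += [b0 + timedelta(days=1)]
        if (c, t) in ((Comparator.GT, True), (Comparator.LE, False)):
            candidates += [one_more]
    candidates += list(default_candidates)
    out = [b for b in candidates if _age_ok(b, as_of, age_targets)]
    if not out:
        for k in range(0, 19 * 366):  # exhaustive day grid, ages 0-19 y
            b = as_of - timedelta(days=k)
            if _age_ok(b, as_of, age_targets):
                out.append(b)
                break
    return out


def _solve_dose_counts(count_targets) -> List[int]:
    """All small valid-dose counts compatible with the dose-count targets."""
    from .engine import _CMP

    return [
        c for c in range(0, 7)
        if all(_CMP[p.comparator](c, p.count) == target for p, target in count_targets)
    ]


def _build_fixture(rule: Rule, rb: Rulebase, seed: int,
                   overrides: Dict[Tuple[int, ...], bool], tag: str) -> PatientRecord:
    """Construct a determinate PatientRecord for the rule's literals, with
    the literals in ``overrides`` forced to the given truth value."""
    category = rb.category(rule.vaccine_category)
    series = category.series
    if series is None:
        raise UnsatisfiableRule(rule.id, "category has no series parameters")
    try:
        literals = conjunctive_literals(rule.logic)
    except ValueError as exc:
        raise UnsatisfiableRule(rule.id, str(exc)) from exc
    as_of = FIXTURE_AS_OF
    grace = DEFAULT_GRACE_DAYS

    # effective target truth value per atom
    targets = []
    for path, pred, negated in literals:
        literal_path = path[:-1] if negated else path
        want_literal = overrides.get(literal_path, True)
        targets.append((path, pred, want_literal != negated))

    age_targets = [(p, t) for _, p, t in targets if p.kind is PredicateKind.AGE_CMP]
    count_targets = [(p, t) for _, p, t in targets if p.kind is PredicateKind.DOSE_COUNT_CMP]
    interval_targets = [(p, t) for _, p, t in targets
                        if p.kind is PredicateKind.INTERVAL_SINCE_DOSE_CMP]
    prior_targets = {p.reference_dose: t for _, p, t in targets
                     if p.kind is PredicateKind.PRIOR_DOSE_VALID}
    cond_targets = [(p, t) for _, p, t in targets
                    if p.kind in (PredicateKind.CONDITION_PRESENT,
                                  PredicateKind.CONDITION_ABSENT)]

    count_options = _solve_dose_counts(count_targets)
    if not count_options:
        raise UnsatisfiableRule(rule.id, "contradictory dose-count predicates")

    needs_doses = count_options[-1] > 0 or prior_targets or interval_targets
    defaults = []
    if series.doses[0].min_age is not None and needs_doses:
        base = _back_shift(as_of, series.doses[0].min_age)
        # leave room between the minimum-age anniversary and as_of for the
        # required number of valid doses
        defaults += [base - timedelta(days=365 * j) for j in (2, 0, 1, 3, 4)]
    defaults += [as_of - timedelta(days=int(365.25 * y)) for y in (5, 2, 10, 15, 1)]
    births = _birth_candidates(as_of, age_targets, defaults)
    if not births:
        raise UnsatisfiableRule(rule.id, "contradictory age predicates")

    needed_len = max(
        [p.reference_dose for p, t in interval_targets if t], default=0
    )

    def make_labels(k: int) -> List[bool]:
        # True = valid slot, False = deliberately invalid administered dose
        max_prior = max(prior_targets, default=0)
        labels: List[bool] = []
        n_valid = 0
        pos = 1
        while n_valid < k or pos <= max(max_prior, needed_len):
            labels.append(prior_targets.get(pos, n_valid < k))
            n_valid += labels[-1]
            pos += 1
            if pos > 12:  # safety bound
                break
        return labels

    fixed: Dict[int, date] = {}
    for p, t in interval_targets:
        thr = p.threshold
        if (p.comparator is Comparator.GE and t) or (p.comparator is Comparator.LT and not t):
            fixed[p.reference_dose] = _back_shift(as_of, thr)
        elif (p.comparator is Comparator.GE and not t) or (p.comparator is Comparator.LT and t):
            fixed[p.reference_dose] = _back_shift(as_of, thr) + timedelta(days=1)
        elif p.comparator is Comparator.GT:
            anchor = _back_shift(as_of, Duration(thr.value + 1, thr.unit))
            fixed[p.reference_dose] = anchor if t else anchor + timedelta(days=1)
        elif p.comparator is Comparator.LE:
            anchor = _back_shift(as_of, thr)
            fixed[p.reference_dose] = anchor if t else anchor - timedelta(days=1)
        else:  # EQ
            anchor = _back_shift(as_of, thr)
            fixed[p.reference_dose] = anchor if t else anchor + timedelta(days=1)

    cvx = rule.vaccine_codes[0] if rule.vaccine_codes else "03"

    def assign_dates(birth: date, labels: List[bool], shift_days: int) -> List[date]:
        dates: List[date] = []
        prev_valid: Optional[date] = None
        valid_seen = 0
        for i, lab in enumerate(labels, start=1):
            if i in fixed:
                d = fixed[i]
            elif lab:
                spec = series.doses[min(valid_seen, series.size - 1)]
                cands = []
                if spec.min_age is not None:
                    cands.append(add_duration(birth, spec.min_age))
                if spec.min_interval is not None and prev_valid is not None:
                    cands.append(add_duration(prev_valid, spec.min_interval))
                d = max(cands) if cands else birth + timedelta(days=365)
                d = d + timedelta(days=shift_days)
            else:
                first_spec = series.doses[0]
                if prev_valid is None and first_spec.min_age is not None:
                    d = add_duration(birth, first_spec.min_age) - timedelta(days=grace + 30)
                    d = max(d, birth + timedelta(days=1))
                else:
                    d = (dates[-1] if dates else birth) + timedelta(days=3)
            if dates and d <= dates[-1]:
                d = dates[-1] + timedelta(days=1)
            d = min(d, as_of)
            dates.append(d)
            if lab:
                prev_valid = d
                valid_seen += 1
        return dates

    conditions = tuple(
        ConditionEntry(p.code) for p, t in cond_targets
        if (p.kind is PredicateKind.CONDITION_PRESENT) == t
    )
    record_id = f"{rule.id.lower()}-{tag}-s{seed}"

    from .engine import eval_expr, eval_predicate

    overridden_paths = {
        path for path, _, negated in literals
        if (path[:-1] if negated else path) in overrides
    }

    def acceptable(state: EvalState) -> bool:
        # the forced atoms must hit their targets exactly; the rule as a
        # whole must evaluate determinately to the expected value (a forced
        # flip may legitimately drag a logically entangled atom with it,
        # e.g. making a prior dose valid raises the valid-dose count)
        for path, pred, want in targets:
            strict = not overrides or path in overridden_paths
            if strict and eval_predicate(pred, state) is not (
                TriState.TRUE if want else TriState.FALSE
            ):
                return False
        value = eval_expr(rule.logic, state)
        return value is (TriState.FALSE if overrides else TriState.TRUE)

    for k in count_options:
        labels = make_labels(k)
        for birth in births:
            for shift in (0, 30, 90, 180, 365, -7, -30):
                doses = tuple(DoseEvent(cvx, d) for d in assign_dates(birth, labels, shift))
                rec = PatientRecord(
                    id=record_id, birth_date=birth, doses=doses, conditions=conditions,
                    history_completeness=Completeness.COMPLETE,
                )
                state = EvalState(rec, category, as_of, grace)
                if acceptable(state):
                    return rec
    raise UnsatisfiableRule(rule.id, f"could not realize targets {overrides or 'positive'}")


def generate_test_cases(rule: Rule, rb: Rulebase, seed: int = 0) -> List[TestCase]:
    """One boundary positive case plus one minimally perturbed negative case
    per atomic predicate.  Deterministic for a given seed."""
    if not rule.executable or rule.logic is None:
        raise UnsatisfiableRule(rule.id, "rule is not executable")
    literals = conjunctive_literals(rule.logic)
    cases = [TestCase(
        rule_id=rule.id,
        polarity=Polarity.POSITIVE,
        fixture=_build_fixture(rule, rb, seed, {}, "pos"),
        as_of=FIXTURE_AS_OF,
        expected=TriggerResult.FIRED,
    )]
    for i, (path, pred, negated) in enumerate(literals):
        literal_path = path[:-1] if negated else path
        fixture = _build_fixture(rule, rb, seed, {literal_path: False}, f"neg{i}")
        cases.append(TestCase(
            rule_id=rule.id,
            polarity=Polarity.NEGATIVE,
            fixture=fixture,
            as_of=FIXTURE_AS_OF,
            expected=TriggerResult.NOT_FIRED,
            perturbed_predicate=path,
        ))
    return cases


def generate_all_cases(rb: Rulebase, seed: int = 0) -> List[TestCase]:
    """Cases for every executable rule in the rulebase."""
    cases: List[TestCase] = []
    for rule in rb.rules:
        if rule.executable:
            cases.extend(generate_test_cases(rule, rb, seed))
    return cases


def run_test_suite(rb: Rulebase, cases: List[TestCase],
                   grace_days: int = DEFAULT_GRACE_DAYS) -> TestReport:
    """Run cases, each fixture round-tripped through a FHIR R4 JSON bundle."""
    report = TestReport()
    for r in rb.rules:
        if r.executable:
            report.statuses[r.id] = RuleStatus.PENDING
    known = {r.id for r in rb.rules}
    for case in cases:
        if case.rule_id not in known:
            raise UnknownRuleId(case.rule_id)
    for case in cases:
        rule = rb.rule(case.rule_id)
        record = read_fhir_bundle(bundle_json(case.fixture))  # exercise patient_io
        state = EvalState(record, rb.category(rule.vaccine_category), case.as_of, grace_days)
        actual = evaluate_rule(rule, state)
        passed = actual is case.expected
        report.outcomes.append(CaseOutcome(case.rule_id, case.polarity,
                                           case.expected, actual, passed))
    touched: Dict[str, bool] = {}
    for o in report.outcomes:
        touched[o.rule_id] = touched.get(o.rule_id, True) and o.passed
    for rid, all_ok in touched.items():
        report.statuses[rid] = RuleStatus.PASSED if all_ok else RuleStatus.FAILED
    return report


def write_fixtures(cases: List[TestCase], out_dir) -> int:
    """Persist each case fixture as a FHIR bundle JSON file; returns count."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for case in cases:
        (out / f"{case.fixture.id}.json").write_text(bundle_json(case.fixture),
                                                     encoding="utf-8")
    return len(cases)
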