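"""Synthetic hypothetical-patient generation.

Each scenario emulates one of the data-quality situations a forecasting
engine meets in practice: children vaccinated on schedule, children behind
schedule, records with silently missing doses, records explicitly flagged as
unknown, contraindicated patients, and records without a birth date.  The
cohorts are plain FHIR R4 bundles, so they double as engine inputs and as
patient-I/O fixtures.

Dose-date jitter for ON_SCHEDULE is uniform within the recommended window;
DELAYED_CATCHUP shifts each dose later by a uniform 1-24 months.
"""
from __future__ import annotations

import json
import random
import zlib
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .patient_io import Completeness, ConditionEntry, DoseEvent, PatientRecord, bundle_json
from .quantities import Duration, Unit, add_duration
from .rule_model import ActionType, Rulebase, RuleClass, load_rulebase, packaged_rulebase_path
from .logic import PredicateKind, iter_atoms

#: generation reference date (matches the testkit fixture date)
DEFAULT_AS_OF = date(2022, 7, 1)


class ScenarioName(str, Enum):
    ON_SCHEDULE = "ON_SCHEDULE"
    DELAYED_CATCHUP = "DELAYED_CATCHUP"
    INCOMPLETE_HISTORY = "INCOMPLETE_HISTORY"
    UNKNOWN_HISTORY = "UNKNOWN_HISTORY"
    CONTRAINDICATED = "CONTRAINDICATED"
    UNKNOWN_BIRTHDATE = "UNKNOWN_BIRTHDATE"


@dataclass(frozen=True)
class Scenario:
    name: ScenarioName
    age_range_days: Tuple[int, int] = (0, 18 * 365)  # 0-18 years
    missingness: float = 0.5  # INCOMPLETE_HISTORY: per-dose drop probability
    as_of: date = DEFAULT_AS_OF

    def __post_init__(self):
        lo, hi = self.age_range_days
        if not (0 <= lo <= hi):
            raise ValueError("bad age range")
        if not (0.0 <= self.missingness <= 1.0):
            raise ValueError("missingness must be in [0, 1]")


def _contraindication_codes(rb: Rulebase) -> List[str]:
    codes = set()
    for r in rb.rules:
        if (r.executable and r.rule_class is RuleClass.CONTRA_PRECAUTION
                and r.action.type is ActionType.CONTRAINDICATED and r.logic is not None):
            for _, pred in iter_atoms(r.logic):
                if pred.kind is PredicateKind.CONDITION_PRESENT:
                    codes.add(pred.code)
    return sorted(codes)


def _mmr_schedule_doses(birth: date, as_of: date, rng: random.Random,
                        delay_months: int = 0) -> List[DoseEvent]:
    """Past-due MMR doses at valid, jittered dates (empty if none due yet)."""
    doses: List[DoseEvent] = []
    d1_window = (add_duration(birth, Duration(12, Unit.MONTHS)),
                 add_duration(birth, Duration(15, Unit.MONTHS)))
    d1 = d1_window[0] + timedelta(days=rng.randint(0, (d1_window[1] - d1_window[0]).days))
    if delay_months:
        d1 = add_duration(d1, Duration(rng.randint(1, delay_months), Unit.MONTHS))
    # a dose is on the record only once its (possibly delayed) date has passed
    if d1 <= as_of:
        doses.append(DoseEvent("03", d1))
        d2_window = (add_duration(birth, Duration(4, Unit.YEARS)),
                     add_duration(birth, Duration(6, Unit.YEARS)))
        d2 = d2_window[0] + timedelta(days=rng.randint(0, (d2_window[1] - d2_window[0]).days))
        d2 = max(d2, d1 + timedelta(days=28))
        if delay_months:
            d2 = add_duration(d2, Duration(rng.randint(1, delay_months), Unit.MONTHS))
        # routine window runs through age 6; only past-due doses are present
        if d2 <= as_of and add_duration(birth, Duration(7, Unit.YEARS)) <= as_of:
            doses.append(DoseEvent("03", d2))
    return doses


def generate_patient(scenario: Scenario, seed: int,
                     rb: Optional[Rulebase] = None) -> PatientRecord:
    """Deterministic synthetic record satisfying the scenario's contract."""
    # stable per-scenario stream: crc32 is process-independent (unlike hash())
    rng = random.Random((zlib.crc32(scenario.name.value.encode()) << 31) + seed)
    as_of = scenario.as_of
    lo, hi = scenario.age_range_days
    birth = as_of - timedelta(days=rng.randint(lo, hi))
    pid = f"{scenario.name.value.lower().replace('_', '-')}-{seed}"
    name = scenario.name

    if name is ScenarioName.UNKNOWN_BIRTHDATE:
        return PatientRecord(
            id=pid, birth_date=None,
            doses=(DoseEvent("03", as_of - timedelta(days=730)),),
            history_completeness=Completeness.COMPLETE,
        )
    if name is ScenarioName.UNKNOWN_HISTORY:
        return PatientRecord(id=pid, birth_date=birth,
                             history_completeness=Completeness.UNKNOWN)

    doses = _mmr_schedule_doses(birth, as_of, rng)
    if name is ScenarioName.ON_SCHEDULE:
        return PatientRecord(id=pid, birth_date=birth, doses=tuple(doses),
                             history_completeness=Completeness.COMPLETE)
    if name is ScenarioName.DELAYED_CATCHUP:
        doses = _mmr_schedule_doses(birth, as_of, rng, delay_months=24)
        return PatientRecord(id=pid, birth_date=birth, doses=tuple(doses),
                             history_completeness=Completeness.COMPLETE)
    if name is ScenarioName.INCOMPLETE_HISTORY:
        kept = tuple(d for d in doses if rng.random() >= scenario.missingness)
        return PatientRecord(id=pid, birth_date=birth, doses=kept,
                             history_completeness=Completeness.INCOMPLETE)
    if name is ScenarioName.CONTRAINDICATED:
        rb = rb if rb is not None else load_rulebase(packaged_rulebase_path())
        codes = _contraindication_codes(rb)
        code = codes[rng.randrange(len(codes))]
        return PatientRecord(
            id=pid, birth_date=birth, doses=tuple(doses),
            conditions=(ConditionEntry(code),),
            history_completeness=Completeness.COMPLETE,
        )
    raise ValueError(name)  # pragma: no cover


@dataclass
class CohortResult:
    records: List[PatientRecord]
    manifest: List[dict] = field(default_factory=list)


def generate_cohort(mix: Dict[ScenarioName, int], seed: int,
                    out_dir=None, rb: Optional[Rulebase] = None,
                    as_of: date = DEFAULT_AS_OF) -> CohortResult:
    """Generate sum(mix.values()) records; optionally write FHIR bundles plus
    a cohort manifest listing the scenario of each patient."""
    result = CohortResult(records=[])
    rng = random.Random(seed)
    for name in sorted(mix, key=lambda s: s.value):
        count = mix[name]
        if count < 0:
            raise ValueError("scenario counts must be >= 0")
        scenario = Scenario(name, as_of=as_of)
        for _ in range(count):
            sub_seed = rng.randrange(2**31)
            rec = generate_patient(scenario, sub_seed, rb=rb)
            result.records.append(rec)
            result.manifest.append({"id": rec.id, "scenario": name.value,
                                    "file": f"{rec.id}.json"})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in result.records:
            (out / f"{rec.id}.json").write_text(bundle_json(rec), encoding="utf-8")
        (out / "cohort.json").write_text(
            json.dumps(result.manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
    return result
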