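"""Rule data model, rulebase directory format, validation and counting.

A rulebase is a directory::

    manifest.json            # category rows, declared per-class counts, series parameters
    rules/<category-slug>.csv  # one delimited file per category row, one rule per line

Each CSV row is one *singular* rule: exactly one condition expression and
exactly one action.  The manifest mirrors the schedule's summary table: one
row per vaccine-category with declared counts for the three rule classes
(regular/catch-up, medical conditions/special situations,
contraindication/precaution); a class the schedule does not use for a
category is recorded as an explicit 0.
"""
from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .errors import (
    DuplicateRuleId,
    LogicParseError,
    MalformedRuleFile,
    MissingManifest,
    UnknownCategory,
    UnknownCategoryReference,
)
from .logic import (
    COMPARATOR_KINDS,
    Expr,
    format_logic,
    iter_atoms,
    parse_logic,
)
from .quantities import Duration

__all__ = [
    "RuleClass", "ActionType", "TimingOffset", "TimingWindow", "Action",
    "DoseSpec", "SeriesSpec", "VaccineCategory", "Manifest", "Rule",
    "Rulebase", "GroupBy", "Violation", "ValidationReport",
    "load_rulebase", "validate_rulebase", "count_rules", "serialize_tabular",
    "parse_rules_csv", "packaged_rulebase_path",
]

CSV_COLUMNS = [
    "rule_id", "vaccine_category", "vaccine_codes", "rule_class", "logic",
    "action_type", "dose_number", "timing_earliest", "timing_recommended",
    "timing_latest", "description", "citation", "executable", "ontology_tag",
]


class RuleClass(str, Enum):
    """The schedule summary's three-way rule partition."""

    REGULAR_CATCHUP = "regular_catchup"
    MEDICAL_CONDITION = "medical_condition"
    CONTRA_PRECAUTION = "contra_precaution"


class ActionType(str, Enum):
    RECOMMEND_DOSE = "RECOMMEND_DOSE"
    SCHEDULE_FOLLOWUP = "SCHEDULE_FOLLOWUP"
    CONTRAINDICATED = "CONTRAINDICATED"
    PRECAUTION = "PRECAUTION"
    SERIES_COMPLETE = "SERIES_COMPLETE"
    INSUFFICIENT_DATA = "INSUFFICIENT_DATA"


@dataclass(frozen=True)
class TimingOffset:
    """A date anchor plus offset: ``birth+12 mo``, ``dose1+28 d``, ``prev_dose+6 mo``."""

    anchor: str  # "birth", "prev_dose", or "dose<k>"
    offset: Duration

    def __str__(self) -> str:
        return f"{self.anchor}+{self.offset}"

    @classmethod
    def parse(cls, text: str) -> "TimingOffset":
        anchor, _, rest = text.partition("+")
        anchor = anchor.strip()
        ok = anchor in ("birth", "prev_dose") or (
            anchor.startswith("dose") and anchor[4:].isdigit() and int(anchor[4:]) >= 1
        )
        if not ok or not rest:
            raise ValueError(f"cannot parse timing offset {text!r}")
        return cls(anchor, Duration.parse(rest))


@dataclass(frozen=True)
class TimingWindow:
    earliest: Optional[TimingOffset] = None
    recommended: Optional[TimingOffset] = None
    latest: Optional[TimingOffset] = None


@dataclass(frozen=True)
class Action:
    """The single consequence of a rule.

    Invariants (checked by :func:`validate_rulebase`, not the constructor, so
    that invalid data can be represented and reported): RECOMMEND_DOSE carries
    ``dose_number``; CONTRAINDICATED / PRECAUTION carry no timing.
    """

    type: ActionType
    dose_number: Optional[int] = None
    timing: Optional[TimingWindow] = None


@dataclass(frozen=True)
class DoseSpec:
    """Series parameters for one dose slot (units as stated by the source)."""

    min_age: Optional[Duration] = None
    min_interval: Optional[Duration] = None  # from the previous valid dose
    routine: Optional[Duration] = None       # routine age (offset from birth)
    routine_latest: Optional[Duration] = None


@dataclass(frozen=True)
class SeriesSpec:
    size: int
    doses: Tuple[DoseSpec, ...]


@dataclass(frozen=True)
class VaccineCategory:
    """One row of the schedule's summary table."""

    name: str
    slug: str
    disease_group: str
    abbreviations: Tuple[str, ...]
    vaccines: Tuple[str, ...]
    counts: Dict[RuleClass, int] = field(default_factory=dict)
    executable: bool = False
    series: Optional[SeriesSpec] = None


@dataclass(frozen=True)
class Rule:
    id: str
    vaccine_category: str  # category slug
    vaccine_codes: Tuple[str, ...]  # CVX codes this rule may recommend
    rule_class: RuleClass
    logic: Optional[Expr]
    action: Action
    description: str = ""
    citation: str = ""
    executable: bool = False
    ontology_tag: Optional[str] = None


@dataclass(frozen=True)
class Manifest:
    schedule_version: str
    counts: Dict[str, Dict[RuleClass, int]]  # category slug -> class -> declared count

    def category_total(self, slug: str) -> int:
        return sum(self.counts[slug].values())

    def grand_total(self) -> int:
        return sum(self.category_total(s) for s in self.counts)


@dataclass
class Rulebase:
    schedule_version: str
    categories: List[VaccineCategory]
    rules: List[Rule]
    manifest: Manifest

    def category(self, slug_or_name: str) -> VaccineCategory:
        for c in self.categories:
            if slug_or_name in (c.slug, c.name):
                return c
        raise UnknownCategory(slug_or_name)

    def rules_for(self, slug: str) -> List[Rule]:
        return [r for r in self.rules if r.vaccine_category == slug]

    def rule(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)

    @property
    def vaccines(self) -> List[str]:
        seen: Dict[str, None] = {}
        for c in self.categories:
            for v in c.vaccines:
                seen.setdefault(v, None)
        return list(seen)

    @property
    def disease_groups(self) -> List[str]:
        seen: Dict[str, None] = {}
        for c in self.categories:
            seen.setdefault(c.disease_group, None)
        return list(seen)


# --- loading ----------------------------------------------------------------

def packaged_rulebase_path() -> Path:
    """Location of the rulebase shipped inside the package."""
    return Path(__file__).parent / "data" / "rulebase"


def _parse_duration_opt(val) -> Optional[Duration]:
    return None if val in (None, "") else Duration.parse(val)


def _category_from_json(obj: dict) -> VaccineCategory:
    series = None
    if obj.get("series"):
        s = obj["series"]
        series = SeriesSpec(
            size=int(s["size"]),
            doses=tuple(
                DoseSpec(
                    min_age=_parse_duration_opt(d.get("min_age")),
                    min_interval=_parse_duration_opt(d.get("min_interval")),
                    routine=_parse_duration_opt(d.get("routine")),
                    routine_latest=_parse_duration_opt(d.get("routine_latest")),
                )
                for d in s["doses"]
            ),
        )
    counts = {RuleClass(k): int(v) for k, v in obj["counts"].items()}
    for rc in RuleClass:  # absent class -> explicit 0 (the table prints "-")
        counts.setdefault(rc, 0)
    return VaccineCategory(
        name=obj["name"],
        slug=obj["slug"],
        disease_group=obj.get("disease_group", obj["name"]),
        abbreviations=tuple(obj.get("abbreviations", ())),
        vaccines=tuple(obj["vaccines"]),
        counts=counts,
        executable=bool(obj.get("executable", False)),
        series=series,
    )


def _rule_from_row(row: dict, path, line: int) -> Rule:
    def fail(msg):
        raise MalformedRuleFile(path, line, msg)

    for col in CSV_COLUMNS:
        if row.get(col) is None:
            fail(f"missing column {col!r}")
    rid = row["rule_id"].strip()
    if not rid:
        fail("empty rule_id")
    try:
        rule_class = RuleClass(row["rule_class"].strip())
    except ValueError:
        fail(f"unknown rule_class {row['rule_class']!r}")
    try:
        action_type = ActionType(row["action_type"].strip())
    except ValueError:
        fail(f"unknown action_type {row['action_type']!r}")
    executable = row["executable"].strip().lower()
    if executable not in ("true", "false"):
        fail(f"executable must be true/false, got {row['executable']!r}")
    logic = None
    if row["logic"].strip():
        try:
            logic = parse_logic(row["logic"].strip())
        except LogicParseError as exc:
            fail(f"bad logic: {exc}")
    dose_number = None
    if row["dose_number"].strip():
        try:
            dose_number = int(row["dose_number"])
        except ValueError:
            fail(f"bad dose_number {row['dose_number']!r}")
    timing_vals = {}
    for key in ("earliest", "recommended", "latest"):
        cell = row[f"timing_{key}"].strip()
        if cell:
            try:
                timing_vals[key] = TimingOffset.parse(cell)
            except ValueError as exc:
                fail(str(exc))
    timing = TimingWindow(**timing_vals) if timing_vals else None
    return Rule(
        id=rid,
        vaccine_category=row["vaccine_category"].strip(),
        vaccine_codes=tuple(c for c in row["vaccine_codes"].split("|") if c),
        rule_class=rule_class,
        logic=logic,
        action=Action(action_type, dose_number=dose_number, timing=timing),
        description=row["description"],
        citation=row["citation"],
        executable=executable == "true",
        ontology_tag=row["ontology_tag"].strip() or None,
    )


def parse_rules_csv(text: str, path="<string>") -> List[Rule]:
    """Parse one category rule file (RFC-4180, UTF-8) into Rule entries."""
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise MalformedRuleFile(path, 1, "empty file")
    if list(reader.fieldnames) != CSV_COLUMNS:
        raise MalformedRuleFile(path, 1, f"bad header {reader.fieldnames!r}")
    rules = []
    for i, row in enumerate(reader, start=2):
        if None in row or any(v is None for v in row.values()):
            raise MalformedRuleFile(path, i, "wrong number of fields")
        rules.append(_rule_from_row(row, path, i))
    return rules


def load_rulebase(path) -> Rulebase:
    """Load and cross-link a rulebase directory.

    Raises MissingManifest, MalformedRuleFile, DuplicateRuleId or
    UnknownCategoryReference; consistency questions that are *data* problems
    (count mismatches, bad actions) are left to :func:`validate_rulebase`.
    """
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.is_file():
        raise MissingManifest(f"no manifest.json in {root}")
    doc = json.loads(manifest_path.read_text(encoding="utf-8"))
    categories = [_category_from_json(c) for c in doc["categories"]]
    slugs = {c.slug for c in categories}
    rules: List[Rule] = []
    seen_ids = set()
    for cat in categories:
        rule_path = root / "rules" / f"{cat.slug}.csv"
        if not rule_path.is_file():
            continue
        for rule in parse_rules_csv(rule_path.read_text(encoding="utf-8"), rule_path):
            if rule.id in seen_ids:
                raise DuplicateRuleId(rule.id)
            seen_ids.add(rule.id)
            if rule.vaccine_category not in slugs:
                raise UnknownCategoryReference(rule.id, rule.vaccine_category)
            rules.append(rule)
    manifest = Manifest(
        schedule_version=doc["schedule_version"],
        counts={c.slug: dict(c.counts) for c in categories},
    )
    return Rulebase(
        schedule_version=doc["schedule_version"],
        categories=categories,
        rules=rules,
        manifest=manifest,
    )


# --- validation -------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    kind: str          # e.g. "ManifestMismatch", "MissingComparator"
    subject: str       # rule id or category slug
    message: str


@dataclass
class ValidationReport:
    violations: List[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __iter__(self):
        return iter(self.violations)

    def __len__(self):
        return len(self.violations)


def validate_rulebase(rb: Rulebase) -> ValidationReport:
    """Check singularity, id uniqueness, manifest arithmetic and predicate
    well-formedness.  Violations are returned as data, never raised."""
    report = ValidationReport()
    add = report.violations.append

    seen = set()
    for r in rb.rules:
        if r.id in seen:
            add(Violation("DuplicateRuleId", r.id, "rule id occurs more than once"))
        seen.add(r.id)

    slugs = {c.slug for c in rb.categories}
    for r in rb.rules:
        if r.vaccine_category not in slugs:
            add(Violation("UnknownCategoryReference", r.id,
                          f"category {r.vaccine_category!r} not in manifest"))

    for r in rb.rules:
        a = r.action
        if a.type is ActionType.RECOMMEND_DOSE and (a.dose_number is None or a.dose_number < 1):
            add(Violation("MissingDoseNumber", r.id, "RECOMMEND_DOSE without dose_number >= 1"))
        if a.type in (ActionType.CONTRAINDICATED, ActionType.PRECAUTION) and a.timing is not None:
            add(Violation("TimingOnWithholdAction", r.id,
                          f"{a.type.value} actions carry no dose timing"))
        if r.executable and r.logic is None:
            add(Violation("MissingLogic", r.id, "executable rule without logic"))
        if r.logic is not None:
            for _, pred in iter_atoms(r.logic):
                if pred.kind in COMPARATOR_KINDS and pred.comparator is None:
                    add(Violation("MissingComparator", r.id,
                                  f"{pred.kind.name} atom lacks a comparator"))

    actual: Dict[str, Dict[RuleClass, int]] = {s: {rc: 0 for rc in RuleClass} for s in slugs}
    for r in rb.rules:
        if r.vaccine_category in actual:
            actual[r.vaccine_category][r.rule_class] += 1
    for slug, declared in rb.manifest.counts.items():
        for rc in RuleClass:
            want = declared.get(rc, 0)
            have = actual.get(slug, {}).get(rc, 0)
            if want != have:
                add(Violation("ManifestMismatch", slug,
                              f"{rc.value}: manifest declares {want}, found {have}"))
    return report


# --- counting ---------------------------------------------------------------

class GroupBy(Enum):
    NONE = "none"
    CATEGORY = "category"
    CATEGORY_AND_CLASS = "category_and_class"


_CLASS_LABELS = {
    RuleClass.REGULAR_CATCHUP: "Regular or Catch-up",
    RuleClass.MEDICAL_CONDITION: "Medical Conditions/Special Situations",
    RuleClass.CONTRA_PRECAUTION: "Contraindication/Precaution",
}


def count_rules(rb: Rulebase, group_by: GroupBy = GroupBy.NONE):
    """Count Rule entries.

    NONE returns the grand total (int); CATEGORY a Series indexed by category
    name; CATEGORY_AND_CLASS a DataFrame with one column per rule class plus
    a Total column, in the summary table's layout.
    """
    if group_by is GroupBy.NONE:
        return len(rb.rules)
    per = {c.slug: {rc: 0 for rc in RuleClass} for c in rb.categories}
    for r in rb.rules:
        if r.vaccine_category in per:
            per[r.vaccine_category][r.rule_class] += 1
    names = {c.slug: c.name for c in rb.categories}
    if group_by is GroupBy.CATEGORY:
        return pd.Series(
            {names[s]: sum(v.values()) for s, v in per.items()}, name="Total", dtype=int
        )
    frame = pd.DataFrame(
        [
            {
                "Vaccine Category": names[s],
                **{_CLASS_LABELS[rc]: per[s][rc] for rc in RuleClass},
                "Total": sum(per[s].values()),
            }
            for s in per
        ]
    ).set_index("Vaccine Category")
    return frame


# --- tabular serialization --------------------------------------------------

def _rule_to_row(r: Rule) -> List[str]:
    t = r.action.timing or TimingWindow()
    return [
        r.id,
        r.vaccine_category,
        "|".join(r.vaccine_codes),
        r.rule_class.value,
        format_logic(r.logic) if r.logic is not None else "",
        r.action.type.value,
        "" if r.action.dose_number is None else str(r.action.dose_number),
        "" if t.earliest is None else str(t.earliest),
        "" if t.recommended is None else str(t.recommended),
        "" if t.latest is None else str(t.latest),
        r.description,
        r.citation,
        "true" if r.executable else "false",
        r.ontology_tag or "",
    ]


def serialize_tabular(rb: Rulebase, category: str) -> str:
    """Serialize one category's rules as CSV (RFC-4180, fixed column order).

    Round-trip stable: ``parse_rules_csv(serialize_tabular(rb, c))`` yields
    the same Rule entries.
    """
    cat = rb.category(category)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for r in rb.rules_for(cat.slug):
        writer.writerow(_rule_to_row(r))
    return buf.getvalue()
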