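"""Patient data model and HL7 FHIR R4 (4.0.1) JSON bundle reader/writer.

The FHIR bundle is the virtual layer between whatever EHR produced the data
and the rule engine: only Patient, Immunization, Condition and
AllergyIntolerance resources are modeled; other resource types are skipped
with a logged notice.  The loader never invents data — a missing birthDate
stays missing, and history completeness defaults to UNKNOWN unless the
bundle states otherwise — so downstream evaluation can propagate explicit
uncertainty instead of silently assuming a clean record.

Condition and allergy codes are opaque strings compared exactly against rule
codes; vaccine codes are CVX.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import List, Optional, Tuple

from .errors import MultiplePatientResources, NoPatientResource, UnparseableResource

log = logging.getLogger(__name__)

CVX_SYSTEM = "http://hl7.org/fhir/sid/cvx"
#: extension URL used to round-trip the explicit history-completeness marker
COMPLETENESS_EXT = "urn:immucast:history-completeness"


class DoseStatus(str, Enum):
    COMPLETED = "completed"
    NOT_DONE = "not-done"
    ENTERED_IN_ERROR = "entered-in-error"


class ClinicalStatus(str, Enum):
    ACTIVE = "active"
    RESOLVED = "resolved"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    F = "female"
    M = "male"
    UNKNOWN = "unknown"


class Completeness(str, Enum):
    COMPLETE = "complete"
    INCOMPLETE = "incomplete"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class DoseEvent:
    vaccine_code: str  # CVX
    date: date         # whole calendar date, proleptic Gregorian
    status: DoseStatus = DoseStatus.COMPLETED


@dataclass(frozen=True)
class ConditionEntry:
    code: str
    clinical_status: ClinicalStatus = ClinicalStatus.ACTIVE
    onset: Optional[date] = None

    def __post_init__(self):
        if not self.code:
            raise ValueError("condition code must be non-empty")


@dataclass(frozen=True)
class PatientRecord:
    id: str
    birth_date: Optional[date] = None
    sex: Sex = Sex.UNKNOWN
    doses: Tuple[DoseEvent, ...] = ()
    conditions: Tuple[ConditionEntry, ...] = ()
    allergies: Tuple[ConditionEntry, ...] = ()
    history_completeness: Completeness = Completeness.UNKNOWN

    def __post_init__(self):
        # doses kept sorted by date (stable for same-day events)
        object.__setattr__(
            self, "doses", tuple(sorted(self.doses, key=lambda d: d.date))
        )

    def completed_doses(self) -> Tuple[DoseEvent, ...]:
        return tuple(d for d in self.doses if d.status is DoseStatus.COMPLETED)


# --- FHIR JSON mapping ------------------------------------------------------

def _parse_date(text: str, rid: str) -> date:
    try:
        return date.fromisoformat(text[:10])
    except ValueError as exc:
        raise UnparseableResource(rid, f"bad date {text!r}") from exc


def _first_code(codeable: Optional[dict]) -> Optional[str]:
    if not codeable:
        return None
    for coding in codeable.get("coding", []):
        if coding.get("code"):
            return coding["code"]
    return codeable.get("text")


def _condition_entry(res: dict) -> ConditionEntry:
    rid = res.get("id", "?")
    code = _first_code(res.get("code"))
    if not code:
        raise UnparseableResource(rid, "no code")
    status_code = _first_code(res.get("clinicalStatus"))
    try:
        status = ClinicalStatus(status_code) if status_code else ClinicalStatus.UNKNOWN
    except ValueError:
        status = ClinicalStatus.UNKNOWN
    onset = res.get("onsetDateTime")
    return ConditionEntry(
        code=code,
        clinical_status=status,
        onset=_parse_date(onset, rid) if onset else None,
    )


def read_fhir_bundle(document) -> PatientRecord:
    """Map a FHIR R4 JSON Bundle (dict or JSON text) to a PatientRecord.

    The bundle must contain exactly one Patient resource.
    """
    if isinstance(document, (str, bytes)):
        document = json.loads(document)
    entries = [e.get("resource", {}) for e in document.get("entry", [])]
    patients = [r for r in entries if r.get("resourceType") == "Patient"]
    if not patients:
        raise NoPatientResource("bundle has no Patient resource")
    if len(patients) > 1:
        raise MultiplePatientResources(f"bundle has {len(patients)} Patient resources")
    pat = patients[0]
    pid = pat.get("id", "patient")
    birth = pat.get("birthDate")
    try:
        sex = Sex(pat.get("gender", "unknown"))
    except ValueError:
        sex = Sex.UNKNOWN
    completeness = Completeness.UNKNOWN
    for ext in pat.get("extension", []):
        if ext.get("url") == COMPLETENESS_EXT:
            try:
                completeness = Completeness(ext.get("valueCode"))
            except ValueError:
                pass

    doses: List[DoseEvent] = []
    conditions: List[ConditionEntry] = []
    allergies: List[ConditionEntry] = []
    for res in entries:
        rtype = res.get("resourceType")
        rid = res.get("id", "?")
        if rtype == "Patient":
            continue
        if rtype == "Immunization":
            code = _first_code(res.get("vaccineCode"))
            if not code:
                raise UnparseableResource(rid, "Immunization without vaccineCode")
            when = res.get("occurrenceDateTime") or res.get("occurrenceString")
            if not when:
                raise UnparseableResource(rid, "Immunization without occurrence date")
            try:
                status = DoseStatus(res.get("status", "completed"))
            except ValueError as exc:
                raise UnparseableResource(rid, f"bad status {res.get('status')!r}") from exc
            doses.append(DoseEvent(code, _parse_date(when, rid), status))
        elif rtype == "Condition":
            conditions.append(_condition_entry(res))
        elif rtype == "AllergyIntolerance":
            allergies.append(_condition_entry(res))
        elif rtype:
            log.info("ignoring unmodeled resource type %s (id %s)", rtype, rid)
    return PatientRecord(
        id=pid,
        birth_date=_parse_date(birth, pid) if birth else None,
        sex=sex,
        doses=tuple(doses),
        conditions=tuple(conditions),
        allergies=tuple(allergies),
        history_completeness=completeness,
    )


def _condition_resource(rtype: str, rid: str, entry: ConditionEntry) -> dict:
    res = {
        "resourceType": rtype,
        "id": rid,
        "code": {"coding": [{"code": entry.code}]},
    }
    if entry.clinical_status is not ClinicalStatus.UNKNOWN:
        res["clinicalStatus"] = {"coding": [{"code": entry.clinical_status.value}]}
    if entry.onset is not None:
        res["onsetDateTime"] = entry.onset.isoformat()
    return res


def write_fhir_bundle(record: PatientRecord) -> dict:
    """Serialize a PatientRecord as a FHIR R4 JSON Bundle (collection).

    Inverse of :func:`read_fhir_bundle` on all modeled fields.
    """
    pat = {"resourceType": "Patient", "id": record.id}
    if record.birth_date is not None:
        pat["birthDate"] = record.birth_date.isoformat()
    if record.sex is not Sex.UNKNOWN:
        pat["gender"] = record.sex.value
    pat["extension"] = [
        {"url": COMPLETENESS_EXT, "valueCode": record.history_completeness.value}
    ]
    entries = [{"resource": pat}]
    for i, d in enumerate(record.doses, start=1):
        entries.append({
            "resource": {
                "resourceType": "Immunization",
                "id": f"{record.id}-imm-{i}",
                "status": d.status.value,
                "vaccineCode": {"coding": [{"system": CVX_SYSTEM, "code": d.vaccine_code}]},
                "occurrenceDateTime": d.date.isoformat(),
                "patient": {"reference": f"Patient/{record.id}"},
            }
        })
    for i, c in enumerate(record.conditions, start=1):
        entries.append({"resource": _condition_resource("Condition", f"{record.id}-cond-{i}", c)})
    for i, a in enumerate(record.allergies, start=1):
        entries.append({"resource": _condition_resource("AllergyIntolerance", f"{record.id}-alg-{i}", a)})
    return {"resourceType": "Bundle", "type": "collection", "entry": entries}


def bundle_json(record: PatientRecord) -> str:
    """Deterministic (sorted-key) JSON text for a record's bundle."""
    return json.dumps(write_fhir_bundle(record), indent=2, sort_keys=True)
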