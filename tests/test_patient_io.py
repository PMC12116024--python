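"""FHIR R4 bundle mapping and round-trip identity."""
import json
from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

from immucast.errors import (
    MultiplePatientResources,
    NoPatientResource,
    UnparseableResource,
)
from immucast.patient_io import (
    ClinicalStatus,
    Completeness,
    ConditionEntry,
    DoseEvent,
    DoseStatus,
    PatientRecord,
    Sex,
    bundle_json,
    read_fhir_bundle,
    write_fhir_bundle,
)


def bundle(*resources):
    return {"resourceType": "Bundle", "type": "collection",
            "entry": [{"resource": r} for r in resources]}


PATIENT = {"resourceType": "Patient", "id": "p1", "birthDate": "2020-01-01"}


def test_basic_mapping():
    rec = read_fhir_bundle(bundle(
        PATIENT,
        {"resourceType": "Immunization", "id": "i1", "status": "completed",
         "vaccineCode": {"coding": [{"code": "03"}]},
         "occurrenceDateTime": "2021-01-05"},
    ))
    assert rec.id == "p1"
    assert rec.birth_date == date(2020, 1, 1)
    assert rec.doses == (DoseEvent("03", date(2021, 1, 5), DoseStatus.COMPLETED),)
    assert rec.history_completeness is Completeness.UNKNOWN  # never defaulted


def test_not_done_dose_is_kept_but_flagged():
    rec = read_fhir_bundle(bundle(
        PATIENT,
        {"resourceType": "Immunization", "id": "i1", "status": "not-done",
         "vaccineCode": {"coding": [{"code": "03"}]},
         "occurrenceDateTime": "2021-01-05"},
    ))
    assert rec.doses[0].status is DoseStatus.NOT_DONE
    assert rec.completed_doses() == ()


def test_missing_birth_date_stays_missing():
    rec = read_fhir_bundle(bundle({"resourceType": "Patient", "id": "p1"}))
    assert rec.birth_date is None


def test_condition_and_allergy_mapping():
    rec = read_fhir_bundle(bundle(
        PATIENT,
        {"resourceType": "Condition", "id": "c1",
         "code": {"coding": [{"code": "PREGNANCY"}]},
         "clinicalStatus": {"coding": [{"code": "active"}]},
         "onsetDateTime": "2022-01-01"},
        {"resourceType": "AllergyIntolerance", "id": "a1",
         "code": {"coding": [{"code": "ANAPHYLAXIS-GELATIN"}]}},
    ))
    assert rec.conditions == (ConditionEntry("PREGNANCY", ClinicalStatus.ACTIVE,
                                             date(2022, 1, 1)),)
    assert rec.allergies[0].clinical_status is ClinicalStatus.UNKNOWN


def test_unmodeled_resources_are_ignored():
    rec = read_fhir_bundle(bundle(PATIENT, {"resourceType": "Observation", "id": "o1"}))
    assert rec.doses == () and rec.conditions == ()


def test_no_patient_resource():
    with pytest.raises(NoPatientResource):
        read_fhir_bundle(bundle())


def test_multiple_patient_resources():
    with pytest.raises(MultiplePatientResources):
        read_fhir_bundle(bundle(PATIENT, dict(PATIENT, id="p2")))


def test_unparseable_immunization_names_resource():
    with pytest.raises(UnparseableResource) as exc:
        read_fhir_bundle(bundle(
            PATIENT,
            {"resourceType": "Immunization", "id": "bad1", "status": "completed",
             "occurrenceDateTime": "2021-01-05"},
        ))
    assert exc.value.resource_id == "bad1"


def test_doses_sorted_on_load():
    rec = PatientRecord(
        id="x", birth_date=date(2020, 1, 1),
        doses=(DoseEvent("03", date(2022, 1, 1)), DoseEvent("03", date(2021, 1, 1))),
    )
    assert [d.date for d in rec.doses] == [date(2021, 1, 1), date(2022, 1, 1)]


def test_minimal_record_round_trip():
    rec = PatientRecord(id="only-id")
    doc = write_fhir_bundle(rec)
    assert "birthDate" not in doc["entry"][0]["resource"]
    assert read_fhir_bundle(doc) == rec


# --- property: round-trip identity over arbitrary records -------------------

dates = st.dates(min_value=date(2004, 1, 1), max_value=date(2022, 12, 31))
codes = st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789-", min_size=1,
                max_size=12)
entries = st.builds(
    ConditionEntry,
    code=codes,
    clinical_status=st.sampled_from(list(ClinicalStatus)),
    onset=st.one_of(st.none(), dates),
)
records = st.builds(
    PatientRecord,
    id=st.text(alphabet="abcdefghijklmnopqrstuvwxyz0123456789", min_size=1, max_size=12),
    birth_date=st.one_of(st.none(), dates),
    sex=st.sampled_from(list(Sex)),
    doses=st.tuples() | st.lists(
        st.builds(DoseEvent, vaccine_code=st.sampled_from(["03", "94", "21", "56"]),
                  date=dates, status=st.sampled_from(list(DoseStatus))),
        max_size=6).map(tuple),
    conditions=st.lists(entries, max_size=3).map(tuple),
    allergies=st.lists(entries, max_size=3).map(tuple),
    history_completeness=st.sampled_from(list(Completeness)),
)


@given(records)
@settings(max_examples=150, deadline=None)
def test_fhir_round_trip_identity(rec):
    assert read_fhir_bundle(write_fhir_bundle(rec)) == rec
    # and via the deterministic JSON text form
    assert read_fhir_bundle(bundle_json(rec)) == rec


@given(records)
@settings(max_examples=50, deadline=None)
def test_bundle_json_is_deterministic(rec):
    assert bundle_json(rec) == bundle_json(rec)
    json.loads(bundle_json(rec))  # well-formed JSON
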