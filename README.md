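# immucast

Machine-processable childhood immunization rules with an unknown-aware
forecasting engine over HL7 FHIR R4 patient bundles.

Clinical decision support for vaccination is usually rebuilt site by site,
even though everyone starts from the same source: the CDC/ACIP recommended
child and adolescent immunization schedule. `immucast` encodes that schedule
(≤18 years, 2022 edition) as a shareable, diff-friendly rulebase of
*singular* rules — one condition, one action per rule — and ships the
machinery a CDSS developer, health-IT vendor or informatics educator needs
around it:

- **`rule_model`** — the rulebase format (a JSON manifest plus one CSV file
  per vaccine category), loading, validation, counting and tabular export.
  The shipped rulebase covers 19 vaccines in 13 disease categories with 465
  rules partitioned into three classes: regular/catch-up, medical
  conditions/special situations, and contraindication/precaution.
  MMR (28 rules) and dengue (9 rules) are fully executable; the remaining
  categories ship as manifest-exact structured placeholders.
- **`patient_io`** — a patient model (doses, conditions, allergies, explicit
  history-completeness marker) that round-trips to FHIR R4 (4.0.1) JSON
  bundles of Patient / Immunization / Condition / AllergyIntolerance
  resources. Vaccine coding is CVX.
- **`engine`** — three-valued (Kleene) rule evaluation: a predicate over
  data the record does not contain is UNKNOWN, not false, and surfaces as an
  explicit INSUFFICIENT_DATA recommendation. Dose validity (minimum age,
  minimum interval, 4-day grace period) is computed at run time from dates,
  never from a precomputed table, and ≥ vs > age thresholds are honored at
  the granularity the schedule states them in.
- **`testkit`** — per-rule positive/negative test-case generation at
  predicate boundaries, with a runner that round-trips every fixture through
  a FHIR bundle before evaluating it.
- **`synth`** — deterministic synthetic cohorts (on-schedule, delayed,
  incomplete/unknown history, contraindicated, unknown birth date).
- **`chartgen`** — DOT decision charts, one per vaccine, with a fixed
  five-color convention (blue to-do, green condition, red contraindication,
  orange follow-up, purple vaccine).
- **`immucast`** (CLI) — `forecast`, `stats`, `validate-rules`,
  `test-rules`, `export-chart`, `synth`.

## The evaluation model

A rule is `logic → action`, where `logic` is a tree over atomic predicates
(age comparisons, valid-dose counts, intervals since a dose, condition
presence/absence, prior-dose validity, season windows) combined with
AND/OR/NOT under Kleene's strong three-valued logic:

    AND(F, ·) = F      OR(T, ·) = T      NOT(U) = U

A recorded dose counts toward its series iff it was given no earlier than
(minimum age − grace) and (minimum interval from the previous valid dose −
grace). Ages are whole calendar units with end-of-month clamping: a child
born January 31 reaches "12 months" on the last day of the following
January... regardless of how many days that is. Per category, a fired
contraindication rule suppresses every dose recommendation; if nothing fires
but some rule is indeterminate, the output is INSUFFICIENT_DATA.

## Worked example

```python
from datetime import date
from immucast import PatientRecord, Completeness, forecast, load_rulebase, packaged_rulebase_path

rb = load_rulebase(packaged_rulebase_path())
child = PatientRecord(id="demo", birth_date=date(2021, 6, 1),
                      history_completeness=Completeness.COMPLETE)
for rec in forecast(child, rb, as_of=date(2022, 7, 1)):
    print(rec.vaccine_category, rec.action.value, rec.dose_number,
          rec.earliest_date, rec.fired_rule_ids)
```

prints

```
mmr RECOMMEND_DOSE 1 2022-06-01 ('MMR-R01', 'MMR-R11', 'MMR-R13')
```

a 13-month-old with no recorded doses is due MMR dose 1, and has been since
the 12-month anniversary (2022-06-01). The fired-rule ids are the routine
12–15-month rule plus the two rules that independently reach the same
action (the revaccinate-invalid-dose rule, vacuously applicable at zero
doses, and the MMRV-option rule). The same record with an
`ANAPHYLAXIS-NEOMYCIN` allergy entry instead yields `CONTRAINDICATED` with
no dates; with `history_completeness=UNKNOWN` it yields
`INSUFFICIENT_DATA`, because an empty dose list in an incomplete record is
not evidence of zero doses.

From the shell:

```
immucast stats                      # category x class counts, totals row 465
immucast forecast patient.json --as-of 2022-07-01 --format json
immucast test-rules --seed 1        # per-rule positive/negative cases
immucast export-chart --out-dir charts   # 19 DOT files
```

## Regenerating the rulebase

The shipped CSVs under `src/immucast/data/rulebase/` are generated by
`python scripts/build_rulebase.py`, which is the single source of truth for
the encoded schedule content.

## Scope

Pediatric (≤18 years) schedule only; no EHR/FHIR-server integration, no CQL
or ELM generation, no terminology-service lookups (value sets are bundled),
and no ontology reasoning (rules carry an optional free-text ontology tag).
See `docs/methods.md` for the modeling decisions and limitations.
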