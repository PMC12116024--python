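# Methods

## What the rulebase encodes

The source is the CDC/ACIP recommended child and adolescent immunization
schedule, ≤18 years, 2022 edition — the routine table, the catch-up table,
and the contraindications/precautions appendix. The schedule is written for
clinicians, so much of its logic is implicit (footnotes, annotations about
valid and invalid doses, "≥" vs ">" age boundaries). The rulebase makes
that logic explicit as *singular* rules: each rule is one conjunctive
condition and exactly one action, so a rule either fires or it does not,
and a test case can target it individually.

The summary table of the encoding has 15 category rows (the two
tetanus-containing rows — DTaP/DT for young children and Tdap/Td for
adolescents — and the two meningococcal rows are separate rows of the same
disease group), 13 distinct disease categories, 19 vaccine products, and
465 rules partitioned as 200 regular/catch-up, 157 medical
conditions/special situations, and 108 contraindication/precaution.
Brand-level variants (MenACWY-D/-CRM/-TT, MenB-4C/-FHbp, DT/Td, Twinrix,
tOPV) are modeled as abbreviations of one product, which is how the
19-product list is obtained; MMRV is a distinct product credited to both
the MMR and varicella series (CVX 94 appears in both value sets).

Two categories are fully executable:

- **MMR** (28 rules: 16/2/10). The regular/catch-up class covers the routine
  12–15-month and 4–6-year doses, the age-banded catch-up rows, minimum
  4-week interval handling (including repeat-the-dose rules via
  `PRIOR_DOSE_VALID`), the MMRV product option with its 12-year age cap and
  3-month recommended interval, series completion, and documented evidence
  of immunity. The two special-situation rules are the 6–11-month
  international-travel dose (which does not count toward the series — it
  fails the 12-month minimum age by construction) and HIV infection without
  severe immunosuppression. The ten contraindication/precaution rules are
  condition-code lookups (anaphylaxis to a prior dose or component, severe
  immunodeficiency, pregnancy, ... and four precautions).
- **Dengue, DEN4CYD** (9 rules: 2/0/7). Eligibility (age 9–16, laboratory
  confirmed previous infection, endemic residence) starts the 0/6/12-month
  series; a follow-up rule schedules each next dose 6 months after the
  previous one. The schedule's "absence of laboratory confirmation" is
  encoded as a *documented seronegative* condition code: under complete
  histories an absence-based predicate would mark every routine child
  dengue-contraindicated, whereas the intended semantics is "do not start
  the series without confirmation", which the eligibility rule already
  enforces.

The other 13 rows ship as manifest-exact placeholder rows
(`executable=false`, no logic), preserving the counts while their
structured encodings are pending. Counting, validation, serialization and
charting treat them as first-class rules; the engine and testkit skip them.

## File format

A rulebase directory is `manifest.json` plus `rules/<slug>.csv` (RFC-4180,
UTF-8, fixed 14-column order). Logic is stored as a compact prefix
notation, e.g. `AND(AGE_GE[12 mo], DOSE_COUNT_EQ[0])`; the comparator is
part of the atom name so that ≥ and > can never be silently conflated.
Durations keep their stated unit at rest (`28 d`, `12 mo`, `9 y`) because
"12 months" is a calendar anniversary, not 365 days. The exact column set
is this package's own definition. The shipped files are generated by
`scripts/build_rulebase.py` and committed, so the content is reviewable as
plain text diffs.

## Evaluation semantics

**Three-valued logic.** Missing information is endemic in immunization
records: histories may be incomplete, conditions unrecorded, birth dates
absent. Every atomic predicate therefore evaluates to TRUE, FALSE or
UNKNOWN, combined by Kleene's strong tables. The load-bearing choices:

- Age predicates with an unknown birth date are UNKNOWN.
- `CONDITION_PRESENT[c]` is TRUE only for an active entry with code `c`
  (conditions and allergies are both searched; codes are opaque strings
  matched exactly). When the code is absent, the result is FALSE only if
  `history_completeness=COMPLETE`; otherwise UNKNOWN — absence of evidence
  is not evidence of absence.
- The set of possible valid-dose counts is an interval `[lo, hi]`: `lo`
  counts doses proven valid, `hi` adds doses of unknown validity and is
  unbounded unless the history is complete. A dose-count predicate is
  TRUE/FALSE only if it holds for all/none of the interval.
- `INTERVAL_SINCE_DOSE[n]` with fewer than `n` recorded doses is FALSE (an
  interval from a dose never recorded satisfies no bound); rules always
  pair interval atoms with dose-count atoms, which carry the
  incomplete-history uncertainty.
- `PRIOR_DOSE_VALID[n]` with no n-th administered dose is FALSE.

**Whole-unit comparisons.** Ages and intervals are compared in whole units
of the threshold: "≥ 12 mo" is true on the 12-month same-day-of-month
anniversary (clamped to month end), "> 12 mo" only from 13 whole months.
Day and week thresholds use exact day arithmetic.

**Dose validity.** Computed at evaluation time from recorded dates and the
category's series parameters (`manifest.json`): a completed dose is valid
iff administered at ≥ (minimum age − grace) and ≥ (minimum interval from
the previous valid dose − grace). The grace period defaults to 4 days —
the conventional ACIP tolerance, an external-knowledge default since the
source table prints no number — and is configurable down to 0. NOT_DONE
and ENTERED_IN_ERROR doses never count; same-day duplicates count once
(the later record wins, earlier ones are flagged `duplicate-same-day`);
doses beyond the series size are flagged rather than credited.

**Conflict resolution** (per category, deterministic): fired
CONTRAINDICATED rules of the contraindication class dominate everything; a
complete series (by fired rule or by count) is next; then the
lowest-numbered recommended outstanding dose (ties by rule id), with
`earliest_date = max(minimum-age date, minimum-interval date from the last
valid dose)`; then scheduled follow-ups; then bare precautions; and if
nothing fired but something was indeterminate, an explicit
INSUFFICIENT_DATA. Fired precautions alongside a recommendation are
reported in the status note rather than suppressing the dose. A category
whose rules are all determinately inapplicable (e.g. dengue for a child
with no dengue history) produces no output row at all, which keeps routine
forecasts uncluttered.

## Patient I/O

Only FHIR R4 (4.0.1) JSON is supported, and only the four modeled resource
types are read; others are skipped with a logged notice. The mapping is
intentionally small and hand-written against the R4 field names
(`birthDate`, `vaccineCode.coding[].code`, `occurrenceDateTime`,
`clinicalStatus`), with the explicit history-completeness marker carried in
a Patient extension (`urn:immucast:history-completeness`) so that records
round-trip without loss. The loader never invents data: missing birth
dates stay missing and completeness defaults to UNKNOWN. Dates are whole
proleptic-Gregorian dates; time zones are ignored. CVX value sets are
bundled (`data/valuesets.yaml`) rather than fetched from a terminology
service.

## Test-case generation

For each executable rule (kept, by construction, as a conjunction of
possibly negated atoms) the testkit builds one positive fixture that
satisfies every atom at its boundary — ages exactly on a ≥ threshold,
intervals at exactly the minimum — and one negative fixture per atom,
perturbing only that atom minimally: birth shifted one day past the
threshold, an interval one day short, a condition code removed. Fixtures
are solved by candidate enumeration (boundary birth dates, feasible
valid-dose counts, fixed interval anchors) and verified against the engine
itself before being emitted; a rule with contradictory atoms raises
`UnsatisfiableRule`. One deliberate wrinkle: forcing `PRIOR_DOSE_VALID[n]`
true moves dose *n* to a valid date, which is the minimal change to the
*record* even though a dose-count atom flips with it; the acceptance check
is therefore "the perturbed atom hits its target and the rule determinately
does not fire". The runner serializes every fixture to a FHIR bundle and
re-reads it before evaluating, so patient I/O is exercised on 100% of
cases. Pass/fail/pending status is tracked per rule, rendered with the
same green/red/yellow convention the charts use.

## Synthetic cohorts

Scenarios state contracts, not distributions: ON_SCHEDULE records carry
every past-due MMR dose at a valid date jittered uniformly within the
recommended window; DELAYED_CATCHUP shifts each dose 1–24 months late
(uniform); INCOMPLETE_HISTORY drops each dose with probability 0.5 and
marks the record INCOMPLETE; UNKNOWN_HISTORY and UNKNOWN_BIRTHDATE are the
explicit-unknown cases; CONTRAINDICATED draws an active condition code from
the rulebase's own executable contraindication rules. Ages are uniform over
0–18 years at the generation date (2022-07-01, matching the testkit).
Generation is deterministic per (scenario, seed) via a crc32-derived
stream, and cohort bundles are byte-identical across runs. What these
cohorts do **not** emulate: realistic demographic structure, co-occurring
conditions, multi-vaccine histories beyond MMR, recording errors or
free-text noise — so passing tests show the engine implements the encoded
schedule faithfully, not that it is robust to arbitrary real-world records.

## Verification strategy

Unit and property tests (hypothesis, fixed profiles) cover calendar
arithmetic against a brute-force calendar-walk oracle, logic parsing
round-trips, FHIR round-trip identity, Kleene algebra laws,
contraindication dominance, monotone series progress and determinism. The
engine's end-to-end behavior is checked against an *independently*
hand-coded MMR decision table (naive month arithmetic, flat if/else rules,
no shared code) over a grid of ~2,400 synthetic patients: monthly ages 0–18
years × dose histories (none; valid first dose; too-early dose; late first
dose; complete series; short-interval second dose) × contraindication
on/off. `scripts/acceptance.py` re-runs all of this from scratch and
reports the measured numbers.

## Known limitations

- Only MMR and dengue evaluate; the other 13 category rows are counted,
  validated, serialized and charted but not executable.
- Pneumococcal series-completeness logic ("age-appropriate complete
  vaccination") is genuinely ambiguous in the source and deliberately not
  encoded.
- `INTERVAL_SINCE_DOSE` references administered-dose order, which for
  exotic histories (an invalid dose *after* the valid one being referenced)
  can anchor on a different dose than a clinician would pick; the shipped
  rules guard these atoms with dose-count conjuncts.
- The engine recommends one category action per run; it does not plan
  multi-visit sequences or co-administration spacing.
- Chart edge semantics (dashed product links, condition→action arrows) are
  this package's own convention; DOT output is checked against the grammar
  the exporter emits, not rendered.
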