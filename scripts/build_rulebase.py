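"""Regenerate the rulebase shipped in src/immucast/data/rulebase/.

The manifest mirrors the CDC 2022 child & adolescent schedule summary (15
category rows, 13 disease groups, 19 vaccine products, 465 rules).  MMR and
dengue are fully executable singular encodings; the other categories ship
manifest-exact placeholder rows pending executable encoding.

Run from the repository root:  python scripts/build_rulebase.py
"""
from __future__ import annotations

import csv
import json
from pathlib import Path

OUT = Path(__file__).resolve().parent.parent / "src" / "immucast" / "data" / "rulebase"

COLUMNS = [
    "rule_id", "vaccine_category", "vaccine_codes", "rule_class", "logic",
    "action_type", "dose_number", "timing_earliest", "timing_recommended",
    "timing_latest", "description", "citation", "executable", "ontology_tag",
]

SCHEDULE_VERSION = "CDC child & adolescent immunization schedule, <=18 years, 2022"

# (slug, name, disease_group, abbreviations, vaccines, (regular, medical, contra), executable)
CATEGORIES = [
    ("dengue", "Dengue", "Dengue", ["DEN4CYD"], ["DEN4CYD"], (2, 0, 7), True),
    ("dtap", "Diphtheria, tetanus, and acellular pertussis",
     "Diphtheria, tetanus, and pertussis", ["DTaP", "DT"], ["DTaP"], (16, 14, 7), False),
    ("hib", "Haemophilus influenzae type b", "Haemophilus influenzae type b",
     ["Hib"], ["Hib"], (16, 20, 4), False),
    ("hepa", "Hepatitis A", "Hepatitis A", ["HepA", "Twinrix"], ["HepA"], (6, 2, 4), False),
    ("hepb", "Hepatitis B", "Hepatitis B", ["HepB"], ["HepB"], (8, 14, 3), False),
    ("hpv", "Human papillomavirus", "Human papillomavirus", ["HPV"], ["HPV"], (15, 18, 2), False),
    ("influenza", "Influenza (inactivated and live and attenuated)", "Influenza",
     ["IIV4", "LAIV4"], ["IIV4", "LAIV4"], (13, 0, 33), False),
    ("mmr", "Measles, mumps, and rubella", "Measles, mumps, and rubella",
     ["MMR", "MMRV"], ["MMR", "MMRV"], (16, 2, 10), True),
    ("menacwy", "Meningococcal serogroups A, C, W, and Y", "Meningococcal",
     ["MenACWY-D", "MenACWY-CRM", "MenACWY-TT"], ["MenACWY"], (12, 34, 5), False),
    ("menb", "Meningococcal serogroup B", "Meningococcal",
     ["MenB-4C", "MenB-FHbp"], ["MenB"], (8, 8, 4), False),
    ("pneumococcal", "Pneumococcal 13-valent conjugate, 23-valent polysaccharide",
     "Pneumococcal", ["PCV13", "PPSV23"], ["PCV13", "PPSV23"], (20, 30, 4), False),
    ("polio", "Poliovirus (inactivated)", "Poliovirus",
     ["IPV", "tOPV"], ["IPV"], (33, 6, 3), False),
    ("rotavirus", "Rotavirus", "Rotavirus", ["RV1", "RV5"], ["RV1", "RV5"], (11, 0, 8), False),
    ("tdap", "Tetanus, diphtheria, and acellular pertussis",
     "Diphtheria, tetanus, and pertussis", ["Tdap", "Td"], ["Tdap"], (12, 9, 6), False),
    ("varicella", "Varicella", "Varicella", ["VAR", "MMRV"], ["VAR", "MMRV"], (12, 0, 8), False),
]

SERIES = {
    "mmr": {
        "size": 2,
        "doses": [
            {"min_age": "12 mo", "routine": "12 mo", "routine_latest": "15 mo"},
            {"min_interval": "28 d", "routine": "4 y", "routine_latest": "6 y"},
        ],
    },
    "dengue": {
        "size": 3,
        "doses": [
            {"min_age": "9 y", "routine": "9 y"},
            {"min_interval": "6 mo"},
            {"min_interval": "6 mo"},
        ],
    },
}

SCHED_CITE = "CDC Child & Adolescent Immunization Schedule 2022, Table 1"
CATCHUP_CITE = "CDC Child & Adolescent Immunization Schedule 2022, Table 2 (catch-up)"
NOTES_CITE = "CDC Child & Adolescent Immunization Schedule 2022, Notes"
APPENDIX_CITE = "CDC Child & Adolescent Immunization Schedule 2022, Appendix (contraindications and precautions)"


def rule(rid, cat, codes, cls, logic, action, dose="", t_earliest="", t_recommended="",
         t_latest="", desc="", cite=SCHED_CITE, executable="true", tag=""):
    return [rid, cat, codes, cls, logic, action, dose, t_earliest, t_recommended,
            t_latest, desc, cite, executable, tag]


MMR_RULES = [
    rule("MMR-R01", "mmr", "03|94", "regular_catchup",
         "AND(AGE_GE[12 mo], AGE_LT[16 mo], DOSE_COUNT_EQ[0])",
         "RECOMMEND_DOSE", "1", "birth+12 mo", "birth+12 mo", "birth+15 mo",
         "Routine first dose at 12 through 15 months."),
    rule("MMR-R02", "mmr", "03|94", "regular_catchup",
         "AND(AGE_LT[12 mo], DOSE_COUNT_EQ[0])",
         "SCHEDULE_FOLLOWUP", "1", "birth+12 mo", "birth+12 mo", "",
         "Under 12 months: schedule dose 1 at the first birthday."),
    rule("MMR-R03", "mmr", "03|94", "regular_catchup",
         "AND(AGE_GE[16 mo], AGE_LT[4 y], DOSE_COUNT_EQ[0])",
         "RECOMMEND_DOSE", "1", "birth+12 mo", "", "",
         "Catch-up first dose, 16 months through 3 years.", CATCHUP_CITE),
    rule("MMR-R04", "mmr", "03|94", "regular_catchup",
         "AND(AGE_GE[4 y], AGE_LT[7 y], DOSE_COUNT_EQ[0])",
         "RECOMMEND_DOSE", "1", "birth+12 mo", "", "",
         "Catch-up first dose at 4 through 6 years.", CATCHUP_CITE),
    rule("MMR-R05", "mmr", "03", "regular_catchup",
         "AND(AGE_GE[7 y], DOSE_COUNT_EQ[0])",
         "RECOMMEND_DOSE", "1", "birth+12 mo", "", "",
         "Catch-up first dose at 7 through 18 years.", CATCHUP_CITE),
    rule("MMR-R06", "mmr", "03|94", "regular_catchup",
         "AND(DOSE_COUNT_EQ[1], AGE_LT[4 y])",
         "SCHEDULE_FOLLOWUP", "2", "birth+4 y", "birth+4 y", "birth+6 y",
         "One valid dose before age 4: schedule dose 2 for the 4-6-year visit."),
    rule("MMR-R07", "mmr", "03|94", "regular_catchup",
         "AND(DOSE_COUNT_EQ[1], AGE_GE[4 y], AGE_LT[7 y], INTERVAL_SINCE_DOSE_GE[1, 28 d])",
         "RECOMMEND_DOSE", "2", "prev_dose+28 d", "birth+4 y", "birth+6 y",
         "Routine second dose at 4 through 6 years."),
    rule("MMR-R08", "mmr", "03", "regular_catchup",
         "AND(DOSE_COUNT_EQ[1], AGE_GE[7 y], INTERVAL_SINCE_DOSE_GE[1, 28 d])",
         "RECOMMEND_DOSE", "2", "prev_dose+28 d", "", "",
         "Catch-up second dose at 7 through 18 years; minimum interval 4 weeks.",
         CATCHUP_CITE),
    rule("MMR-R09", "mmr", "03|94", "regular_catchup",
         "AND(DOSE_COUNT_EQ[1], AGE_GE[4 y], INTERVAL_SINCE_DOSE_LT[1, 28 d])",
         "SCHEDULE_FOLLOWUP", "2", "prev_dose+28 d", "prev_dose+28 d", "",
         "Dose 2 due, but the 4-week minimum interval has not yet elapsed.",
         CATCHUP_CITE),
    rule("MMR-R10", "mmr", "03|94", "regular_catchup",
         "DOSE_COUNT_GE[2]",
         "SERIES_COMPLETE", "", "", "", "",
         "Two valid doses: series complete."),
    rule("MMR-R11", "mmr", "03|94", "regular_catchup",
         "AND(DOSE_COUNT_EQ[0], NOT(PRIOR_DOSE_VALID[1]), AGE_GE[12 mo])",
         "RECOMMEND_DOSE", "1", "birth+12 mo", "", "",
         "A dose given before 12 months of age does not count; revaccinate.",
         NOTES_CITE),
    rule("MMR-R12", "mmr", "03|94", "regular_catchup",
         "AND(DOSE_COUNT_EQ[1], NOT(PRIOR_DOSE_VALID[2]), AGE_GE[4 y], INTERVAL_SINCE_DOSE_GE[1, 28 d])",
         "RECOMMEND_DOSE", "2", "prev_dose+28 d", "", "",
         "A second dose given <4 weeks after the first does not count; repeat it.",
         NOTES_CITE),
    rule("MMR-R13", "mmr", "94", "regular_catchup",
         "AND(AGE_GE[12 mo], AGE_LE[12 y], DOSE_COUNT_EQ[0])",
         "RECOMMEND_DOSE", "1", "birth+12 mo", "", "",
         "MMRV may be used for dose 1 through age 12 (credits MMR and varicella).",
         NOTES_CITE),
    rule("MMR-R14", "mmr", "94", "regular_catchup",
         "AND(DOSE_COUNT_EQ[1], AGE_GE[4 y], AGE_LE[12 y], INTERVAL_SINCE_DOSE_GE[1, 3 mo])",
         "RECOMMEND_DOSE", "2", "prev_dose+3 mo", "birth+4 y", "birth+6 y",
         "MMRV option for dose 2 through age 12; recommended interval >=3 months.",
         NOTES_CITE),
    rule("MMR-R15", "mmr", "03|94", "regular_catchup",
         "CONDITION_PRESENT[EVIDENCE-OF-IMMUNITY-MMR]",
         "SERIES_COMPLETE", "", "", "", "",
         "Documented evidence of immunity: no further doses needed.", NOTES_CITE),
    rule("MMR-R16", "mmr", "03", "regular_catchup",
         "AND(DOSE_COUNT_EQ[1], AGE_GT[12 y], INTERVAL_SINCE_DOSE_GE[1, 28 d])",
         "RECOMMEND_DOSE", "2", "prev_dose+28 d", "", "",
         "Older than 12 years: use MMR (not MMRV) for the remaining dose.",
         NOTES_CITE),
    rule("MMR-M01", "mmr", "03", "medical_condition",
         "AND(CONDITION_PRESENT[INTERNATIONAL-TRAVEL], AGE_GE[6 mo], AGE_LT[12 mo], DOSE_COUNT_EQ[0])",
         "RECOMMEND_DOSE", "1", "birth+6 mo", "", "",
         "Infant 6-11 months traveling internationally: one early dose "
         "(does not count toward the 2-dose series).", NOTES_CITE),
    rule("MMR-M02", "mmr", "03", "medical_condition",
         "AND(CONDITION_PRESENT[HIV-WITHOUT-SEVERE-IMMUNOSUPPRESSION], AGE_GE[12 mo], DOSE_COUNT_EQ[0])",
         "RECOMMEND_DOSE", "1", "birth+12 mo", "", "",
         "HIV infection without severe immunosuppression: 2-dose series from 12 months.",
         NOTES_CITE),
]

_MMR_CONTRA = [
    ("MMR-C01", "ANAPHYLAXIS-PRIOR-MMR-DOSE", "CONTRAINDICATED",
     "Severe allergic reaction (anaphylaxis) after a previous MMR/MMRV dose."),
    ("MMR-C02", "ANAPHYLAXIS-NEOMYCIN", "CONTRAINDICATED",
     "Anaphylaxis to neomycin (vaccine component)."),
    ("MMR-C03", "ANAPHYLAXIS-GELATIN", "CONTRAINDICATED",
     "Anaphylaxis to gelatin (vaccine component)."),
    ("MMR-C04", "SEVERE-IMMUNODEFICIENCY", "CONTRAINDICATED",
     "Severe congenital or acquired immunodeficiency: live vaccine contraindicated."),
    ("MMR-C05", "HIV-SEVERE-IMMUNOSUPPRESSION", "CONTRAINDICATED",
     "HIV infection with severe immunosuppression."),
    ("MMR-C06", "PREGNANCY", "CONTRAINDICATED",
     "Pregnancy or planned pregnancy within 4 weeks."),
    ("MMR-C07", "FAMILY-HISTORY-ALTERED-IMMUNOCOMPETENCE", "PRECAUTION",
     "Family history of altered immunocompetence: defer until immune status verified."),
    ("MMR-C08", "RECENT-ANTIBODY-CONTAINING-PRODUCT", "PRECAUTION",
     "Recent antibody-containing blood product: defer (interval up to 11 months)."),
    ("MMR-C09", "MODERATE-SEVERE-ACUTE-ILLNESS", "PRECAUTION",
     "Moderate or severe acute illness: defer until resolved."),
    ("MMR-C10", "HISTORY-THROMBOCYTOPENIA", "PRECAUTION",
     "History of thrombocytopenia or thrombocytopenic purpura."),
]
MMR_RULES += [
    rule(rid, "mmr", "03|94", "contra_precaution",
         f"CONDITION_PRESENT[{code}]", action, desc=desc, cite=APPENDIX_CITE)
    for rid, code, action, desc in _MMR_CONTRA
]

DENGUE_RULES = [
    rule("DEN-R01", "dengue", "56", "regular_catchup",
         "AND(AGE_GE[9 y], AGE_LE[16 y], CONDITION_PRESENT[DENGUE-PREVIOUS-INFECTION-LAB-CONFIRMED], "
         "CONDITION_PRESENT[RESIDENCE-DENGUE-ENDEMIC-AREA], DOSE_COUNT_EQ[0])",
         "RECOMMEND_DOSE", "1", "birth+9 y", "", "",
         "Seropositive 9-16-year-olds living in endemic areas: start the 3-dose "
         "series (0, 6, 12 months)."),
    rule("DEN-R02", "dengue", "56", "regular_catchup",
         "AND(DOSE_COUNT_GE[1], DOSE_COUNT_LE[2])",
         "SCHEDULE_FOLLOWUP", "", "prev_dose+6 mo", "prev_dose+6 mo", "",
         "Next dose 6 months after the previous dose."),
]
_DEN_CONTRA = [
    ("DEN-C01", "DENGUE-SERONEGATIVE", "CONTRAINDICATED",
     "Documented absence of previous dengue infection: do not vaccinate."),
    ("DEN-C02", "ANAPHYLAXIS-PRIOR-DEN4CYD-DOSE", "CONTRAINDICATED",
     "Severe allergic reaction after a previous DEN4CYD dose."),
    ("DEN-C03", "ANAPHYLAXIS-DEN4CYD-COMPONENT", "CONTRAINDICATED",
     "Anaphylaxis to a DEN4CYD component."),
    ("DEN-C04", "SEVERE-IMMUNODEFICIENCY", "CONTRAINDICATED",
     "Severe congenital or acquired immunodeficiency: live vaccine contraindicated."),
    ("DEN-C05", "HIV-SEVERE-IMMUNOSUPPRESSION", "CONTRAINDICATED",
     "HIV infection with severe immunosuppression."),
    ("DEN-C06", "PREGNANCY", "CONTRAINDICATED", "Pregnancy."),
    ("DEN-C07", "MODERATE-SEVERE-ACUTE-ILLNESS", "PRECAUTION",
     "Moderate or severe acute illness: defer until resolved."),
]
DENGUE_RULES += [
    rule(rid, "dengue", "56", "contra_precaution",
         f"CONDITION_PRESENT[{code}]", action, desc=desc, cite=APPENDIX_CITE)
    for rid, code, action, desc in _DEN_CONTRA
]


def placeholder_rules(slug, name, vaccines, counts):
    """Manifest-exact placeholder rows for a not-yet-executable category."""
    from_cls = [
        ("regular_catchup", "R", counts[0], "RECOMMEND_DOSE", "1"),
        ("medical_condition", "M", counts[1], "RECOMMEND_DOSE", "1"),
        ("contra_precaution", "C", counts[2], "CONTRAINDICATED", ""),
    ]
    rows = []
    for cls, letter, n, action, dose in from_cls:
        for i in range(1, n + 1):
            rows.append(rule(
                f"{slug.upper()}-{letter}{i:02d}", slug, "", cls, "", action, dose,
                desc=f"{name}: {cls.replace('_', '/')} rule {i} of {n} "
                     "(structured encoding pending; counted in the manifest).",
                executable="false",
            ))
    return rows


def main():
    (OUT / "rules").mkdir(parents=True, exist_ok=True)
    manifest = {"schedule_version": SCHEDULE_VERSION, "categories": []}
    all_rules = {"mmr": MMR_RULES, "dengue": DENGUE_RULES}
    for slug, name, group, abbrevs, vaccines, counts, executable in CATEGORIES:
        entry = {
            "name": name,
            "slug": slug,
            "disease_group": group,
            "abbreviations": abbrevs,
            "vaccines": vaccines,
            "counts": {
                "regular_catchup": counts[0],
                "medical_condition": counts[1],
                "contra_precaution": counts[2],
            },
            "executable": executable,
        }
        if slug in SERIES:
            entry["series"] = SERIES[slug]
        manifest["categories"].append(entry)
        rows = all_rules.get(slug) or placeholder_rules(slug, name, vaccines, counts)
        with open(OUT / "rules" / f"{slug}.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(COLUMNS)
            w.writerows(rows)
    with open(OUT / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    total = sum(sum(c[5]) for c in CATEGORIES)
    print(f"wrote {len(CATEGORIES)} categories, {total} rules, to {OUT}")


if __name__ == "__main__":
    main()
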