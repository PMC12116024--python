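"""Rulebase loading, manifest arithmetic, validation and serialization."""
import dataclasses
import shutil
from pathlib import Path

import pytest

from immucast.errors import (
    DuplicateRuleId,
    MalformedRuleFile,
    MissingManifest,
    UnknownCategory,
    UnknownCategoryReference,
)
from immucast.rule_model import (
    Action,
    ActionType,
    GroupBy,
    Manifest,
    Rule,
    Rulebase,
    RuleClass,
    count_rules,
    load_rulebase,
    packaged_rulebase_path,
    parse_rules_csv,
    serialize_tabular,
    validate_rulebase,
)

# per-class counts of the encoded 2022 schedule summary, keyed by slug
EXPECTED_COUNTS = {
    "dengue": (2, 0, 7),
    "dtap": (16, 14, 7),
    "hib": (16, 20, 4),
    "hepa": (6, 2, 4),
    "hepb": (8, 14, 3),
    "hpv": (15, 18, 2),
    "influenza": (13, 0, 33),
    "mmr": (16, 2, 10),
    "menacwy": (12, 34, 5),
    "menb": (8, 8, 4),
    "pneumococcal": (20, 30, 4),
    "polio": (33, 6, 3),
    "rotavirus": (11, 0, 8),
    "tdap": (12, 9, 6),
    "varicella": (12, 0, 8),
}


def test_shipped_rulebase_matches_schedule_summary(rb):
    assert count_rules(rb) == 465
    assert len(rb.vaccines) == 19
    assert len(rb.disease_groups) == 13
    assert len(rb.categories) == 15
    for slug, (reg, med, contra) in EXPECTED_COUNTS.items():
        cat = rb.category(slug)
        assert cat.counts[RuleClass.REGULAR_CATCHUP] == reg, slug
        assert cat.counts[RuleClass.MEDICAL_CONDITION] == med, slug
        assert cat.counts[RuleClass.CONTRA_PRECAUTION] == contra, slug
        assert len(rb.rules_for(slug)) == reg + med + contra


def test_manifest_arithmetic(rb):
    m = rb.manifest
    assert m.grand_total() == 465
    for slug, counts in EXPECTED_COUNTS.items():
        assert m.category_total(slug) == sum(counts)


def test_count_rules_groupings(rb):
    frame = count_rules(rb, GroupBy.CATEGORY_AND_CLASS)
    mmr = frame.loc["Measles, mumps, and rubella"]
    assert list(mmr) == [16, 2, 10, 28]
    series = count_rules(rb, GroupBy.CATEGORY)
    assert series["Dengue"] == 9
    assert int(series.sum()) == 465
    empty = Rulebase("v", [], [], Manifest("v", {}))
    assert count_rules(empty) == 0


def test_shipped_rulebase_is_valid(rb):
    assert validate_rulebase(rb).ok


def test_mmrv_contributes_to_two_categories(rb):
    assert "MMRV" in rb.category("mmr").vaccines
    assert "MMRV" in rb.category("varicella").vaccines


def test_serialize_round_trip_every_category(rb):
    for cat in rb.categories:
        text = serialize_tabular(rb, cat.slug)
        rules = parse_rules_csv(text)
        assert rules == rb.rules_for(cat.slug)
        assert text.count("\n") == len(rules) + 1  # header + one line per rule


def test_serialize_unknown_category(rb):
    with pytest.raises(UnknownCategory):
        serialize_tabular(rb, "smallpox")


# --- loading errors ---------------------------------------------------------

def test_empty_directory_is_missing_manifest(tmp_path):
    with pytest.raises(MissingManifest):
        load_rulebase(tmp_path)


def _copy_rulebase(tmp_path) -> Path:
    dst = tmp_path / "rb"
    shutil.copytree(packaged_rulebase_path(), dst)
    return dst


def test_duplicate_rule_id_rejected(tmp_path):
    dst = _copy_rulebase(tmp_path)
    mmr = dst / "rules" / "mmr.csv"
    lines = mmr.read_text().splitlines()
    lines.append(lines[1])  # repeat the first data row verbatim
    mmr.write_text("\n".join(lines) + "\n")
    with pytest.raises(DuplicateRuleId):
        load_rulebase(dst)


def test_malformed_rule_file_reports_location(tmp_path):
    dst = _copy_rulebase(tmp_path)
    mmr = dst / "rules" / "mmr.csv"
    lines = mmr.read_text().splitlines()
    lines[3] = lines[3].replace("regular_catchup", "sometimes")
    mmr.write_text("\n".join(lines) + "\n")
    with pytest.raises(MalformedRuleFile) as exc:
        load_rulebase(dst)
    assert exc.value.line == 4
    assert "mmr.csv" in exc.value.path


def test_unknown_category_reference(tmp_path):
    dst = _copy_rulebase(tmp_path)
    mmr = dst / "rules" / "mmr.csv"
    mmr.write_text(mmr.read_text().replace('MMR-R01,mmr,', 'MMR-R01,smallpox,'))
    with pytest.raises(UnknownCategoryReference):
        load_rulebase(dst)


# --- validation completeness: every injected defect is reported -------------

def _clone(rb: Rulebase) -> Rulebase:
    return Rulebase(rb.schedule_version, list(rb.categories), list(rb.rules),
                    rb.manifest)


def _inject_duplicate(rb):
    rb.rules.append(rb.rules[0])
    return "DuplicateRuleId", rb.rules[0].id


def _inject_manifest_mismatch(rb):
    victim = next(r for r in rb.rules if r.vaccine_category == "mmr")
    rb.rules.remove(victim)
    return "ManifestMismatch", "mmr"


def _inject_missing_logic(rb):
    r = rb.rules[0]
    rb.rules[0] = dataclasses.replace(r, logic=None, executable=True)
    return "MissingLogic", r.id


def _inject_bad_action(rb):
    r = next(x for x in rb.rules if x.action.type is ActionType.RECOMMEND_DOSE)
    i = rb.rules.index(r)
    rb.rules[i] = dataclasses.replace(r, action=Action(ActionType.RECOMMEND_DOSE))
    return "MissingDoseNumber", r.id


def _inject_unknown_category(rb):
    r = rb.rules[0]
    rb.rules[0] = dataclasses.replace(r, vaccine_category="smallpox")
    return "UnknownCategoryReference", r.id


@pytest.mark.parametrize("inject", [
    _inject_duplicate,
    _inject_manifest_mismatch,
    _inject_missing_logic,
    _inject_bad_action,
    _inject_unknown_category,
])
def test_validation_names_the_injected_defect(rb, inject):
    broken = _clone(rb)
    kind, subject = inject(broken)
    report = validate_rulebase(broken)
    assert any(v.kind == kind and v.subject == subject for v in report), list(report)


def test_manifest_mismatch_is_a_single_violation(rb):
    broken = _clone(rb)
    _inject_manifest_mismatch(broken)
    mismatches = [v for v in validate_rulebase(broken) if v.kind == "ManifestMismatch"]
    assert len(mismatches) == 1
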