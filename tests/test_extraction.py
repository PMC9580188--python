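"""Report-level resolution: precedence orders, numeric extraction, gating."""

import itertools

import pytest

from hcmnlp import (
    NOT_EVALUATED,
    ConceptMention,
    PipelineConfig,
    extract_numeric,
    parse_report,
    resolve_categorical,
    resolve_diagnosis,
    resolve_location,
    resolve_subtype,
    run_pipeline,
)

from _table1 import CATEGORICAL_EXAMPLES, NUMERIC_EXAMPLES


def mention(status, concept_id="HCM_DIAGNOSIS", label=None, idx=0):
    return ConceptMention(
        concept_id=concept_id, sentence_index=idx, matched_text="x", span=(0, 1),
        assertion=status, triggering_cue="cue" if status != "ASSERTED" else "", label=label,
    )


STATUSES = ("ASSERTED", "NEGATED", "POSSIBLE")


def brute_force_diagnosis(statuses):
    """Independent application of the stated total order YES > POSSIBLE > NO
    > NOT_MENTIONED."""
    for status, out in (("ASSERTED", "YES"), ("POSSIBLE", "POSSIBLE"), ("NEGATED", "NO")):
        if status in statuses:
            return out
    return "NOT_MENTIONED"


def brute_force_categorical(statuses):
    if any(s in ("ASSERTED", "POSSIBLE") for s in statuses):
        return "PRESENT"
    if "NEGATED" in statuses:
        return "ABSENT_NEGATED"
    return "NOT_MENTIONED"


def all_multisets(max_size=3):
    for k in range(max_size + 1):
        yield from itertools.combinations_with_replacement(STATUSES, k)


def test_diagnosis_precedence_matches_brute_force_enumeration():
    for combo in all_multisets():
        got = resolve_diagnosis([mention(s) for s in combo])
        assert got == brute_force_diagnosis(combo), combo


def test_categorical_precedence_matches_brute_force_enumeration():
    for combo in all_multisets():
        got = resolve_categorical([mention(s, "SAM") for s in combo])
        assert got == brute_force_categorical(combo), combo


def test_mixed_statuses_across_sentences_resolve_yes():
    ms = [mention("NEGATED", idx=0), mention("ASSERTED", idx=1)]
    assert resolve_diagnosis(ms) == "YES"


class TestSubtypeAndLocation:
    def test_last_asserted_subtype_wins(self):
        ms = [mention("ASSERTED", "HCM_SUBTYPE", "SIGMOID", idx=0),
              mention("ASSERTED", "HCM_SUBTYPE", "APICAL", idx=2)]
        assert resolve_subtype(ms) == "APICAL"

    def test_negated_subtype_ignored(self):
        ms = [mention("NEGATED", "HCM_SUBTYPE", "SIGMOID")]
        assert resolve_subtype(ms) == "NOT_MENTIONED"

    def test_location_prefers_lvot_on_conflict(self):
        ms = [mention("ASSERTED", "OBSTRUCTION_LOCATION", "MID_VENTRICULAR", idx=0),
              mention("ASSERTED", "OBSTRUCTION_LOCATION", "LVOT", idx=1)]
        assert resolve_location(ms) == "LVOT"
        assert resolve_location(ms[:1]) == "MID_VENTRICULAR"
        assert resolve_location([]) == "NOT_MENTIONED"


class TestNumericExtraction:
    @pytest.mark.parametrize("sentence,concept_id,value,unit", NUMERIC_EXAMPLES)
    def test_worked_examples(self, lexicon, sentence, concept_id, value, unit):
        doc = parse_report("r", sentence)
        nr = extract_numeric(doc, concept_id, lexicon)
        assert nr is not None
        assert nr.value == value and nr.unit == unit
        assert doc.text[nr.source_span[0] : nr.source_span[1]] == nr.raw_text

    def test_cm_converts_to_mm(self, lexicon):
        doc = parse_report("r", "The maximal thickness of the septum is 2.2 cm.")
        nr = extract_numeric(doc, "MAX_LV_WALL_THICKNESS", lexicon)
        assert nr.value == 22.0 and nr.unit == "mm"

    def test_implausible_value_rejected(self, lexicon):
        doc = parse_report("r", "Maximal wall thickness is 220 mm.")
        assert extract_numeric(doc, "MAX_LV_WALL_THICKNESS", lexicon) is None

    def test_missing_unit_skipped(self, lexicon):
        doc = parse_report("r", "Maximal wall thickness is 22 units.")
        assert extract_numeric(doc, "MAX_LV_WALL_THICKNESS", lexicon) is None

    def test_mass_anchor_does_not_steal_mass_index_value(self, lexicon):
        doc = parse_report("r", "LV End Diastolic Mass Index = 186 g/m2.")
        assert extract_numeric(doc, "LV_MASS", lexicon) is None
        assert extract_numeric(doc, "LV_MASS_INDEX", lexicon).value == 186.0

    def test_measurements_section_preferred(self, lexicon):
        text = ("FINDINGS: Maximal wall thickness is 18 mm.\n"
                "MEASUREMENTS: Maximal wall thickness is 22 mm.\n")
        doc = parse_report("r", text)
        assert extract_numeric(doc, "MAX_LV_WALL_THICKNESS", lexicon).value == 22.0

    def test_non_numeric_concept_rejected(self, lexicon):
        doc = parse_report("r", "SAM is present.")
        with pytest.raises(ValueError):
            extract_numeric(doc, "SAM", lexicon)


class TestPipeline:
    def test_all_asserted_example_sentences_in_one_report(self, lexicon):
        sentences = [s + "." for s, _c, a, _l in CATEGORICAL_EXAMPLES if a == "ASSERTED"]
        sentences += [s + "." for s, _c, _v, _u in NUMERIC_EXAMPLES]
        doc = parse_report("all", " ".join(dict.fromkeys(sentences)))
        res = run_pipeline(doc, lexicon)
        assert res.diagnosis == "YES"
        assert res.subtype == "APICAL"  # last-mentioned subtype wins
        assert res.obstruction_location == "LVOT"  # preferred over mid-chamber
        assert all(v == "PRESENT" for v in res.categoricals.values())
        assert res.numerics == {
            "MAX_LV_WALL_THICKNESS": 22.0, "LV_MASS": 426.0, "LV_MASS_INDEX": 186.0,
            "LV_EF": 83.0, "RV_EF": 61.0,
        }

    @pytest.mark.parametrize("text,expected_diag", [
        ("There is no evidence for hypertrophic cardiomyopathy.", "NO"),
        ("The lungs are clear.", "NOT_MENTIONED"),
    ])
    def test_negative_reports_gate_tier2(self, lexicon, text, expected_diag):
        res = run_pipeline(parse_report("r", text), lexicon)
        assert res.diagnosis == expected_diag
        assert res.subtype == NOT_EVALUATED
        assert res.obstruction_location == NOT_EVALUATED
        assert set(res.categoricals.values()) == {NOT_EVALUATED}
        assert set(res.numerics.values()) == {NOT_EVALUATED}

    def test_tier2_runs_on_possible_diagnosis(self, lexicon):
        text = ("Possible hypertrophic cardiomyopathy. "
                "Mitral regurgitation is present. LV Ejection Fraction: 64%.")
        res = run_pipeline(parse_report("r", text), lexicon)
        assert res.diagnosis == "POSSIBLE"
        assert res.categoricals["MITRAL_REGURGITATION"] == "PRESENT"
        assert res.numerics["LV_EF"] == 64.0

    def test_pipeline_is_idempotent(self, lexicon):
        doc = parse_report("r", "Findings consistent with hypertrophic cardiomyopathy. "
                                "Enlarged left atrium. RV Ejection Fraction: 61%.")
        a = run_pipeline(doc, lexicon, PipelineConfig())
        b = run_pipeline(doc, lexicon, PipelineConfig())
        assert a.to_dict() == b.to_dict()
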