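"""Two-tier report-level extraction.

Tier 1 resolves the report's HCM diagnosis status from its diagnosis
mentions.  Tier 2 — run only on diagnosis-positive reports (YES or POSSIBLE)
— resolves seven binary phenotype concepts, two multiclass concepts
(morphologic subtype, obstruction location) and five numeric measurements
with unit normalisation.  Reports that are diagnosis-negative carry an
explicit NOT_EVALUATED marker for every tier-2 field.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .assertion import ASSERTED, NEGATED, POSSIBLE, AssertionConfig, ConceptMention, classify_assertion
from .lexicon import (
    CATEGORICAL_CONCEPTS,
    CONCEPTS,
    DIAGNOSIS_CONCEPT,
    NUMERIC_CONCEPTS,
    NUMERIC_UNITS,
    Lexicon,
    match_concepts,
)
from .report_model import ReportDocument

log = logging.getLogger("hcmnlp")

# diagnosis statuses
YES = "YES"
NO = "NO"
NOT_MENTIONED = "NOT_MENTIONED"
# categorical statuses
PRESENT = "PRESENT"
ABSENT_NEGATED = "ABSENT_NEGATED"
# tier-2 gating marker
NOT_EVALUATED = "NOT_EVALUATED"

DIAGNOSIS_STATUSES = (YES, NO, POSSIBLE, NOT_MENTIONED)

#: default plausibility ranges, canonical units; values outside are logged and dropped
DEFAULT_PLAUSIBILITY = {
    "MAX_LV_WALL_THICKNESS": (3.0, 60.0),
    "LV_MASS": (30.0, 1000.0),
    "LV_MASS_INDEX": (10.0, 400.0),
    "LV_EF": (5.0, 95.0),
    "RV_EF": (5.0, 95.0),
}

#: section preference when one measurement appears several times
SECTION_PREFERENCE = ("MEASUREMENTS", "FINDINGS")


@dataclass
class PipelineConfig:
    assertion: AssertionConfig = field(default_factory=AssertionConfig)
    plausibility: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLAUSIBILITY)
    )
    numeric_tolerance: float = 0.0  # used by evaluation when comparing to gold


@dataclass(frozen=True)
class NumericResult:
    concept_id: str
    value: float
    unit: str
    source_span: tuple[int, int]  # document offsets
    raw_text: str


@dataclass
class ReportResult:
    """Per-report pipeline output: diagnosis plus tier-2 phenotype fields."""

    report_id: str
    diagnosis: str
    subtype: str = NOT_EVALUATED
    obstruction_location: str = NOT_EVALUATED
    categoricals: dict[str, str] = field(default_factory=dict)
    numerics: dict[str, float | str | None] = field(default_factory=dict)
    evidence: dict[str, list[ConceptMention]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "report_id": self.report_id,
            "diagnosis": self.diagnosis,
            "subtype": self.subtype,
            "obstruction_location": self.obstruction_location,
            "categoricals": dict(self.categoricals),
            "numerics": {k: v for k, v in self.numerics.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReportResult":
        return cls(
            report_id=d["report_id"],
            diagnosis=d["diagnosis"],
            subtype=d.get("subtype", NOT_EVALUATED),
            obstruction_location=d.get("obstruction_location", NOT_EVALUATED),
            categoricals=dict(d.get("categoricals", {})),
            numerics=dict(d.get("numerics", {})),
        )


# ---------------------------------------------------------------------------
# Tier-1 / tier-2 resolvers


def resolve_diagnosis(mentions: list[ConceptMention]) -> str:
    """Total order YES > POSSIBLE > NO > NOT_MENTIONED over mention statuses."""
    statuses = {m.assertion for m in mentions}
    if ASSERTED in statuses:
        return YES
    if POSSIBLE in statuses:
        return POSSIBLE
    if NEGATED in statuses:
        return NO
    return NOT_MENTIONED


def resolve_categorical(mentions: list[ConceptMention]) -> str:
    """PRESENT if any asserted-or-hedged mention; else ABSENT_NEGATED if any
    negated; else NOT_MENTIONED."""
    statuses = [m.assertion for m in mentions]
    if any(s in (ASSERTED, POSSIBLE) for s in statuses):
        return PRESENT
    if NEGATED in statuses:
        return ABSENT_NEGATED
    return NOT_MENTIONED


def _positional(m: ConceptMention) -> tuple[int, int]:
    return (m.sentence_index, m.span[0])


def resolve_subtype(mentions: list[ConceptMention]) -> str:
    """Last-asserted morphologic subtype label in document order."""
    labelled = [
        m for m in mentions
        if m.label is not None and m.assertion in (ASSERTED, POSSIBLE)
    ]
    if not labelled:
        return NOT_MENTIONED
    labels = {m.label for m in labelled}
    winner = max(labelled, key=_positional)
    if len(labels) > 1:
        log.warning(json.dumps({
            "event": "subtype_conflict", "labels": sorted(labels), "chosen": winner.label,
        }))
    return winner.label  # type: ignore[return-value]


def resolve_location(mentions: list[ConceptMention]) -> str:
    """LVOT preferred when both locations are asserted."""
    labels = {
        m.label for m in mentions
        if m.label is not None and m.assertion in (ASSERTED, POSSIBLE)
    }
    if "LVOT" in labels:
        if "MID_VENTRICULAR" in labels:
            log.warning(json.dumps({"event": "location_conflict", "chosen": "LVOT"}))
        return "LVOT"
    if "MID_VENTRICULAR" in labels:
        return "MID_VENTRICULAR"
    return NOT_MENTIONED


# ---------------------------------------------------------------------------
# Numeric extraction

# number then an optional unit token (e.g. "22 mm", "426 g", "186 g/m2", "83%")
_NUMBER_RE = re.compile(r"([-+]?\d+(?:\.\d+)?)\s*(%|[A-Za-z][\w/^²]*)?")

#: accepted unit spellings -> factor into the canonical unit
_UNIT_FACTORS: dict[str, dict[str, float]] = {
    "mm": {"mm": 1.0, "millimeter": 1.0, "millimeters": 1.0,
           "cm": 10.0, "centimeter": 10.0, "centimeters": 10.0},
    "g": {"g": 1.0, "gm": 1.0, "gram": 1.0, "grams": 1.0, "kg": 1000.0},
    "g/m2": {"g/m2": 1.0, "g/m^2": 1.0, "g/m²": 1.0, "gm/m2": 1.0, "gm/m^2": 1.0},
    "%": {"%": 1.0, "percent": 1.0},
}

_MAX_ANCHOR_GAP = 80  # chars searched past the anchor for the measurement


def _parse_unit(token: str | None, canonical: str) -> float | None:
    if token is None:
        return None
    tok = token.strip().rstrip(".,;").lower()
    return _UNIT_FACTORS[canonical].get(tok)


def extract_numeric(
    report: ReportDocument,
    concept_id: str,
    lexicon: Lexicon,
    config: PipelineConfig | None = None,
) -> NumericResult | None:
    """Extract one numeric concept from a report, unit-normalised.

    For every anchor-phrase match the first number within the same sentence
    (at most ~80 characters past the anchor) is taken as a candidate; its unit
    must convert to the concept's canonical unit and its value must fall in
    the plausibility range.  Among candidates, MEASUREMENTS beats FINDINGS
    beats first occurrence.
    """
    if CONCEPTS[concept_id].value_kind != "numeric":
        raise ValueError(f"{concept_id} is not a numeric concept")
    if config is None:
        config = PipelineConfig()
    canonical = NUMERIC_UNITS[concept_id]
    lo, hi = config.plausibility.get(concept_id, (float("-inf"), float("inf")))

    candidates: list[tuple[int, int, NumericResult]] = []  # (section_rank, order, result)
    order = 0
    for s_idx, sent in enumerate(report.sentences):
        text = report.sentence_text(sent)
        matches = match_concepts(text, lexicon, s_idx)
        for rm in matches:
            if rm.concept_id != concept_id:
                continue
            # anchor containment: "LV mass" inside "LV mass index" belongs to
            # the longer concept's anchor, not this one
            if any(
                m.concept_id != concept_id
                and CONCEPTS[m.concept_id].value_kind == "numeric"
                and m.span[0] <= rm.span[0]
                and m.span[1] >= rm.span[1]
                and (m.span[1] - m.span[0]) > (rm.span[1] - rm.span[0])
                for m in matches
            ):
                continue
            window = text[rm.span[1] : rm.span[1] + _MAX_ANCHOR_GAP]
            m = _NUMBER_RE.search(window)
            if m is None:
                continue
            factor = _parse_unit(m.group(2), canonical)
            if factor is None:
                log.warning(json.dumps({
                    "event": "numeric_unit_skipped", "report_id": report.report_id,
                    "concept_id": concept_id, "raw": m.group(0).strip(),
                }))
                continue
            value = float(m.group(1)) * factor
            if not (lo <= value <= hi):
                log.warning(json.dumps({
                    "event": "numeric_implausible", "report_id": report.report_id,
                    "concept_id": concept_id, "value": value, "range": [lo, hi],
                }))
                continue
            abs_start = sent.span[0] + rm.span[0]
            abs_end = sent.span[0] + rm.span[1] + m.end()
            rank = (
                SECTION_PREFERENCE.index(sent.section_name)
                if sent.section_name in SECTION_PREFERENCE
                else len(SECTION_PREFERENCE)
            )
            candidates.append((
                rank, order,
                NumericResult(concept_id, value, canonical, (abs_start, abs_end),
                              report.text[abs_start:abs_end]),
            ))
            order += 1
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1]))
    return candidates[0][2]


# ---------------------------------------------------------------------------
# Pipeline


def collect_mentions(
    report: ReportDocument, lexicon: Lexicon, config: PipelineConfig | None = None
) -> dict[str, list[ConceptMention]]:
    """All assertion-classified concept mentions, grouped by concept."""
    if config is None:
        config = PipelineConfig()
    grouped: dict[str, list[ConceptMention]] = {}
    for s_idx, sent in enumerate(report.sentences):
        text = report.sentence_text(sent)
        for rm in match_concepts(text, lexicon, s_idx):
            cm = classify_assertion(rm, text, lexicon, config.assertion, sent.section_name)
            grouped.setdefault(cm.concept_id, []).append(cm)
    return grouped


def run_pipeline(
    report: ReportDocument, lexicon: Lexicon, config: PipelineConfig | None = None
) -> ReportResult:
    """Run both tiers on one parsed report."""
    if config is None:
        config = PipelineConfig()
    mentions = collect_mentions(report, lexicon, config)
    diagnosis = resolve_diagnosis(mentions.get(DIAGNOSIS_CONCEPT, []))

    result = ReportResult(report_id=report.report_id, diagnosis=diagnosis, evidence=mentions)
    if diagnosis in (YES, POSSIBLE):
        result.subtype = resolve_subtype(mentions.get("HCM_SUBTYPE", []))
        result.obstruction_location = resolve_location(mentions.get("OBSTRUCTION_LOCATION", []))
        for cid in CATEGORICAL_CONCEPTS:
            result.categoricals[cid] = resolve_categorical(mentions.get(cid, []))
        for cid in NUMERIC_CONCEPTS:
            nr = extract_numeric(report, cid, lexicon, config)
            result.numerics[cid] = nr.value if nr is not None else None
    else:
        result.subtype = NOT_EVALUATED
        result.obstruction_location = NOT_EVALUATED
        for cid in CATEGORICAL_CONCEPTS:
            result.categoricals[cid] = NOT_EVALUATED
        for cid in NUMERIC_CONCEPTS:
            result.numerics[cid] = NOT_EVALUATED
    return result


# ---------------------------------------------------------------------------
# Results I/O (JSON; NOT_EVALUATED encoded explicitly, never omitted)


def write_results(results: list[ReportResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=1)
        fh.write("\n")


def read_results(path: str | Path) -> list[ReportResult]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return [ReportResult.from_dict(d) for d in data]
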