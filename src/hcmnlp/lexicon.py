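"""Concept lexicon: the 15 phenotype concepts, their phrase patterns, and
sentence-level matching.

The extraction rules are dictionary look-up plus regular-expression pattern
detection.  Each concept owns a set of *target* patterns; assertion handling
additionally uses *negation_cue*, *hedge_cue*, *pseudo_negation* and
*termination* entries (shared rows use the sentinel concept id ``ALL``).
Everything is editable data shipped as a TSV, not code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

# ---------------------------------------------------------------------------
# Concept registry

DIAGNOSIS_CONCEPT = "HCM_DIAGNOSIS"
MULTICLASS_CONCEPTS = ("HCM_SUBTYPE", "OBSTRUCTION_LOCATION")
CATEGORICAL_CONCEPTS = (
    "SAM",
    "MITRAL_REGURGITATION",
    "LV_OBSTRUCTION",
    "APICAL_POUCH",
    "LV_DELAYED_ENHANCEMENT",
    "LA_ENLARGEMENT",
    "RA_ENLARGEMENT",
)
NUMERIC_CONCEPTS = ("MAX_LV_WALL_THICKNESS", "LV_MASS", "LV_MASS_INDEX", "LV_EF", "RV_EF")

#: canonical unit per numeric concept
NUMERIC_UNITS = {
    "MAX_LV_WALL_THICKNESS": "mm",
    "LV_MASS": "g",
    "LV_MASS_INDEX": "g/m2",
    "LV_EF": "%",
    "RV_EF": "%",
}

SUBTYPE_LABELS = ("SIGMOID", "REVERSE_CURVE", "NEUTRAL", "APICAL")
LOCATION_LABELS = ("LVOT", "MID_VENTRICULAR")

VALID_ROLES = ("target", "negation_cue", "hedge_cue", "pseudo_negation", "termination")
ALL_CONCEPTS_SENTINEL = "ALL"


@dataclass(frozen=True)
class Concept:
    concept_id: str
    value_kind: str  # diagnosis | categorical | multiclass | numeric
    value_domain: tuple[str, ...] = ()
    unit: str | None = None


def _build_registry() -> dict[str, Concept]:
    reg = {DIAGNOSIS_CONCEPT: Concept(DIAGNOSIS_CONCEPT, "diagnosis")}
    reg["HCM_SUBTYPE"] = Concept("HCM_SUBTYPE", "multiclass", SUBTYPE_LABELS)
    reg["OBSTRUCTION_LOCATION"] = Concept("OBSTRUCTION_LOCATION", "multiclass", LOCATION_LABELS)
    for cid in CATEGORICAL_CONCEPTS:
        reg[cid] = Concept(cid, "categorical")
    for cid in NUMERIC_CONCEPTS:
        reg[cid] = Concept(cid, "numeric", unit=NUMERIC_UNITS[cid])
    return reg


CONCEPTS: dict[str, Concept] = _build_registry()

#: Table-style row order used for rendered outputs
CONCEPT_ORDER = (
    DIAGNOSIS_CONCEPT,
    "HCM_SUBTYPE",
    "SAM",
    "MITRAL_REGURGITATION",
    "LV_OBSTRUCTION",
    "OBSTRUCTION_LOCATION",
    "APICAL_POUCH",
    "LV_DELAYED_ENHANCEMENT",
    "LA_ENLARGEMENT",
    "RA_ENLARGEMENT",
    "MAX_LV_WALL_THICKNESS",
    "LV_MASS",
    "LV_MASS_INDEX",
    "LV_EF",
    "RV_EF",
)


class LexiconError(ValueError):
    """Raised when a lexicon file fails validation."""


@dataclass(frozen=True)
class LexiconEntry:
    concept_id: str
    pattern: str
    pattern_type: str  # literal | regex
    role: str
    label: str | None = None
    compiled: re.Pattern = field(repr=False, compare=False, default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class RawMatch:
    """One target-pattern hit inside one sentence."""

    concept_id: str
    sentence_index: int
    matched_text: str
    span: tuple[int, int]  # offsets within the sentence text
    label: str | None = None


def _compile_entry(concept_id: str, pattern: str, pattern_type: str, rowno: int) -> re.Pattern:
    if pattern_type == "literal":
        body = r"\s+".join(re.escape(tok) for tok in pattern.split())
        rx = rf"(?<!\w){body}(?!\w)"
    elif pattern_type == "regex":
        rx = pattern
    else:
        raise LexiconError(f"row {rowno}: unknown pattern_type {pattern_type!r}")
    try:
        return re.compile(rx, re.IGNORECASE)
    except re.error as exc:
        raise LexiconError(f"row {rowno}: pattern does not compile: {pattern!r} ({exc})") from exc


class Lexicon:
    """A validated set of lexicon entries, grouped by concept and role."""

    def __init__(self, entries: list[LexiconEntry]):
        if not entries:
            raise LexiconError("no entries")
        self.entries = entries
        self.targets: dict[str, list[LexiconEntry]] = {}
        self.cues: dict[str, dict[str, list[LexiconEntry]]] = {}
        for e in entries:
            if e.role == "target":
                self.targets.setdefault(e.concept_id, []).append(e)
            else:
                self.cues.setdefault(e.concept_id, {}).setdefault(e.role, []).append(e)

    def cue_entries(self, concept_id: str, role: str) -> list[LexiconEntry]:
        """Cues applying to one concept: shared ``ALL`` rows plus its own."""
        out = list(self.cues.get(ALL_CONCEPTS_SENTINEL, {}).get(role, []))
        out.extend(self.cues.get(concept_id, {}).get(role, []))
        return out

    def concepts_with_targets(self) -> list[str]:
        return [cid for cid in CONCEPT_ORDER if cid in self.targets]


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Load and validate a lexicon TSV.

    Columns: concept_id, pattern, pattern_type, role, optional label.
    ``#`` lines are comments.  Unknown concept ids or roles, and
    non-compiling regexes, raise :class:`LexiconError` naming the row.
    """
    if path is None:
        raw = resources.files("hcmnlp.data").joinpath("lexicon.tsv").read_text()
        name = "<default lexicon>"
    else:
        raw = Path(path).read_text(encoding="utf-8")
        name = str(path)

    entries: list[LexiconEntry] = []
    for rowno, line in enumerate(raw.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 4:
            raise LexiconError(f"{name} row {rowno}: expected ≥4 tab-separated columns")
        concept_id, pattern, pattern_type, role = (c.strip() for c in cols[:4])
        label = cols[4].strip() if len(cols) > 4 and cols[4].strip() else None
        if concept_id not in CONCEPTS and concept_id != ALL_CONCEPTS_SENTINEL:
            raise LexiconError(f"{name} row {rowno}: unknown concept_id {concept_id!r}")
        if role not in VALID_ROLES:
            raise LexiconError(f"{name} row {rowno}: unknown role {role!r}")
        if concept_id == ALL_CONCEPTS_SENTINEL and role == "target":
            raise LexiconError(f"{name} row {rowno}: targets must name a concrete concept")
        if label is not None:
            concept = CONCEPTS[concept_id]
            if label not in concept.value_domain:
                raise LexiconError(
                    f"{name} row {rowno}: label {label!r} not in domain of {concept_id}"
                )
        compiled = _compile_entry(concept_id, pattern, pattern_type, rowno)
        entries.append(LexiconEntry(concept_id, pattern, pattern_type, role, label, compiled))
    if not entries:
        raise LexiconError(f"{name}: no entries")
    return Lexicon(entries)


def _leftmost_longest(hits: list[tuple[int, int, LexiconEntry]]) -> list[tuple[int, int, LexiconEntry]]:
    """Resolve overlapping hits: sort by (start, -length), greedily keep."""
    hits.sort(key=lambda h: (h[0], -(h[1] - h[0])))
    kept: list[tuple[int, int, LexiconEntry]] = []
    for h in hits:
        if not kept or h[0] >= kept[-1][1]:
            kept.append(h)
    return kept


def find_cue_spans(sentence_text: str, entries: list[LexiconEntry]) -> list[tuple[int, int, LexiconEntry]]:
    """All non-overlapping leftmost-longest cue hits for the given entries."""
    hits = []
    for e in entries:
        for m in e.compiled.finditer(sentence_text):
            if m.end() > m.start():
                hits.append((m.start(), m.end(), e))
    return _leftmost_longest(hits)


def match_concepts(
    sentence_text: str, lexicon: Lexicon, sentence_index: int = 0
) -> list[RawMatch]:
    """Match every concept's target patterns in one sentence.

    Overlapping matches of the *same* concept resolve leftmost-longest;
    different concepts may overlap freely.  Deterministic for a fixed
    (sentence, lexicon) pair.
    """
    out: list[RawMatch] = []
    for concept_id in lexicon.concepts_with_targets():
        hits = []
        for e in lexicon.targets[concept_id]:
            for m in e.compiled.finditer(sentence_text):
                if m.end() > m.start():
                    hits.append((m.start(), m.end(), e))
        for s, t, e in _leftmost_longest(hits):
            out.append(
                RawMatch(
                    concept_id=concept_id,
                    sentence_index=sentence_index,
                    matched_text=sentence_text[s:t],
                    span=(s, t),
                    label=e.label,
                )
            )
    return out
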