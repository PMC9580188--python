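"""Assertion status classification: ASSERTED, NEGATED, or POSSIBLE.

Given a concept match inside a sentence, decide whether the sentence affirms,
negates, or hedges it, using cue phrases with a bounded token scope, in the
spirit of NegEx/ConText.  The rules:

* default ASSERTED;
* NEGATED when a negation cue precedes the target within ``pre_window`` tokens
  or follows within ``post_window`` tokens ("is not present"), unless a
  pseudo-negation phrase ("not ruled out", "no change in") overlaps the cue or
  a termination token ("but", "however", ";") intervenes;
* POSSIBLE when a hedge cue ("possible", "cannot exclude", "borderline") is in
  scope and no negation applies;
* when both a negation and a hedge cue are in scope, the cue closer to the
  target wins; ties resolve NEGATED.

Classification is a pure function of (sentence text, match, lexicon, config).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .lexicon import Lexicon, LexiconEntry, RawMatch, find_cue_spans

ASSERTED = "ASSERTED"
NEGATED = "NEGATED"
POSSIBLE = "POSSIBLE"

_TOKEN_RE = re.compile(r"\S+")


@dataclass(frozen=True)
class AssertionConfig:
    pre_window: int = 6
    post_window: int = 4


def load_assertion_config(path: str | Path | None = None) -> AssertionConfig:
    if path is None:
        raw = resources.files("hcmnlp.data").joinpath("assertion.yaml").read_text()
    else:
        raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    return AssertionConfig(
        pre_window=int(data.get("pre_window", 6)),
        post_window=int(data.get("post_window", 4)),
    )


@dataclass(frozen=True)
class ConceptMention:
    """A concept match with its resolved assertion status."""

    concept_id: str
    sentence_index: int
    matched_text: str
    span: tuple[int, int]
    assertion: str
    triggering_cue: str = ""
    label: str | None = None
    section_name: str = "UNKNOWN"


def _tokens_between(text: str, start: int, end: int) -> int:
    """Number of whole tokens strictly inside text[start:end]."""
    if end <= start:
        return 0
    return sum(1 for _ in _TOKEN_RE.finditer(text, start, end))


def _has_termination(text: str, start: int, end: int, terms: list[tuple[int, int, LexiconEntry]]) -> bool:
    return any(ts >= start and te <= end for ts, te, _ in terms)


def _overlaps_any(span: tuple[int, int], spans: list[tuple[int, int, LexiconEntry]]) -> bool:
    s, e = span
    return any(ps < e and s < pe for ps, pe, _ in spans)


def classify_assertion(
    match: RawMatch,
    sentence_text: str,
    lexicon: Lexicon,
    config: AssertionConfig | None = None,
    section_name: str = "UNKNOWN",
) -> ConceptMention:
    """Classify one match as ASSERTED / NEGATED / POSSIBLE."""
    if config is None:
        config = AssertionConfig()
    t0, t1 = match.span
    if not (0 <= t0 <= t1 <= len(sentence_text)):
        raise ValueError("match span lies outside sentence text")

    neg = find_cue_spans(sentence_text, lexicon.cue_entries(match.concept_id, "negation_cue"))
    hedge = find_cue_spans(sentence_text, lexicon.cue_entries(match.concept_id, "hedge_cue"))
    pseudo = find_cue_spans(sentence_text, lexicon.cue_entries(match.concept_id, "pseudo_negation"))
    terms = find_cue_spans(sentence_text, lexicon.cue_entries(match.concept_id, "termination"))

    def in_scope(cues: list[tuple[int, int, LexiconEntry]], block_pseudo: bool):
        """Yield (token_distance, cue_text) for cues in scope of the target."""
        for cs, ce, _e in cues:
            if block_pseudo and _overlaps_any((cs, ce), pseudo):
                continue
            if ce <= t0:  # pre-target cue
                gap = _tokens_between(sentence_text, ce, t0)
                if gap <= config.pre_window and not _has_termination(sentence_text, ce, t0, terms):
                    yield gap, sentence_text[cs:ce]
            elif cs >= t1:  # post-target cue
                gap = _tokens_between(sentence_text, t1, cs)
                if gap <= config.post_window and not _has_termination(sentence_text, t1, cs, terms):
                    yield gap, sentence_text[cs:ce]

    neg_hits = sorted(in_scope(neg, block_pseudo=True))
    hedge_hits = sorted(in_scope(hedge, block_pseudo=False))

    assertion, cue = ASSERTED, ""
    if neg_hits and hedge_hits:
        # nearest cue wins; tie resolves to negation
        if neg_hits[0][0] <= hedge_hits[0][0]:
            assertion, cue = NEGATED, neg_hits[0][1]
        else:
            assertion, cue = POSSIBLE, hedge_hits[0][1]
    elif neg_hits:
        assertion, cue = NEGATED, neg_hits[0][1]
    elif hedge_hits:
        assertion, cue = POSSIBLE, hedge_hits[0][1]

    return ConceptMention(
        concept_id=match.concept_id,
        sentence_index=match.sentence_index,
        matched_text=match.matched_text,
        span=match.span,
        assertion=assertion,
        triggering_cue=cue,
        label=match.label,
        section_name=section_name,
    )
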