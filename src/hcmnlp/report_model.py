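"""Sectioned, sentence-segmented report documents and corpus I/O.

A cardiac MR report arrives as narrative text organised in standardized
sections (HISTORY, TECHNIQUE, FINDINGS, MEASUREMENTS, IMPRESSION).  This
module parses raw text into a :class:`ReportDocument` whose sections tile the
text and whose sentences carry stable character offsets, so every downstream
match can be traced back to an exact slice of the original report.

Offsets are 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

SECTION_LABELS = (
    "FINDINGS",
    "IMPRESSION",
    "MEASUREMENTS",
    "HISTORY",
    "TECHNIQUE",
    "UNKNOWN",
)


class ReportParseError(ValueError):
    """Raised when a report or corpus cannot be parsed."""


@dataclass(frozen=True)
class Section:
    """One standardized report section.

    ``header_span`` covers the recognised header text (empty for UNKNOWN
    fallback sections); ``body_span`` covers everything up to the next header.
    """

    name: str
    header_span: tuple[int, int]
    body_span: tuple[int, int]

    @property
    def span(self) -> tuple[int, int]:
        return (self.header_span[0], self.body_span[1])


@dataclass(frozen=True)
class Sentence:
    """A sentence span within the enclosing document's text."""

    span: tuple[int, int]
    section_name: str


@dataclass
class ReportDocument:
    report_id: str
    text: str
    patient_id: str | None = None
    sections: list[Section] = field(default_factory=list)
    sentences: list[Sentence] = field(default_factory=list)

    def sentence_text(self, sentence: Sentence) -> str:
        return self.text[sentence.span[0] : sentence.span[1]]

    def section_body(self, section: Section) -> str:
        return self.text[section.body_span[0] : section.body_span[1]]


# ---------------------------------------------------------------------------
# Section alias configuration


def load_section_aliases(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load the header alias table (normalized label -> header literals).

    With no ``path`` the packaged default table ships; dialects with other
    headers (e.g. "CONCLUSION" for IMPRESSION) are handled by editing the YAML,
    not the code.
    """
    if path is None:
        raw = resources.files("hcmnlp.data").joinpath("section_aliases.yaml").read_text()
    else:
        raw = Path(path).read_text()
    table = yaml.safe_load(raw)
    if not isinstance(table, dict):
        raise ReportParseError("section alias table must be a mapping")
    out: dict[str, list[str]] = {}
    for label, names in table.items():
        label = str(label).upper()
        if label not in SECTION_LABELS or label == "UNKNOWN":
            raise ReportParseError(f"unknown section label in alias table: {label!r}")
        out[label] = [str(n) for n in names]
    return out


def _find_headers(text: str, aliases: dict[str, list[str]]) -> list[tuple[int, int, str]]:
    """Locate section headers as (start, end, label), non-overlapping, sorted.

    A header is an alias that either starts a line and ends with ':' (any
    case), or appears fully uppercase followed by ':' anywhere, or sits fully
    uppercase alone on its own line.
    """
    hits: list[tuple[int, int, str]] = []
    for label, names in aliases.items():
        for name in names:
            esc = re.escape(name)
            esc_upper = re.escape(name.upper())
            for m in re.finditer(rf"(?im)^[ \t]*{esc}[ \t]*:", text):
                hits.append((m.start(), m.end(), label))
            for m in re.finditer(rf"(?<![A-Za-z]){esc_upper}[ \t]*:", text):
                hits.append((m.start(), m.end(), label))
            for m in re.finditer(rf"(?m)^[ \t]*{esc_upper}[ \t]*$", text):
                hits.append((m.start(), m.end(), label))
    # longest-at-position wins, then drop overlaps
    hits.sort(key=lambda h: (h[0], -(h[1] - h[0])))
    kept: list[tuple[int, int, str]] = []
    for h in hits:
        if not kept or h[0] >= kept[-1][1]:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# Sentence segmentation

# tokens whose trailing period never ends a sentence
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "vs", "etc", "fig", "approx", "ca", "st",
    "e.g", "i.e", "resp",
}


def _is_list_marker(text: str, word_start: int, word: str) -> bool:
    """True for numbered-list markers like '1.' at the start of a line."""
    if not word or not word.isdigit():
        return False
    j = word_start - 1
    while j >= 0 and text[j] in " \t":
        j -= 1
    return j < 0 or text[j] == "\n"


def _sentence_boundaries(text: str) -> list[int]:
    """Indices just past each sentence-terminating punctuation mark."""
    bounds: list[int] = []
    for m in re.finditer(r"[.?!]", text):
        i = m.start()
        if text[i] == ".":
            # decimal numbers ("1.5") never split
            if 0 < i < len(text) - 1 and text[i - 1].isdigit() and text[i + 1].isdigit():
                continue
            j = i - 1
            while j >= 0 and (text[j].isalnum() or text[j] == "."):
                j -= 1
            word = text[j + 1 : i].lower()
            if word in _ABBREVIATIONS:
                continue
            if _is_list_marker(text, j + 1, word):
                continue
        rest = text[i + 1 :]
        if rest == "" or re.match(r"\s*$", rest):
            bounds.append(i + 1)
        elif re.match(r"[\"')\]]*\s*\n", rest):
            bounds.append(i + 1)
        elif re.match(r"[\"')\]]*\s+[\"'(\[]*[A-Z0-9]", rest):
            bounds.append(i + 1)
    return bounds


def _segment_body(text: str, base: int, section_name: str) -> list[Sentence]:
    bounds = _sentence_boundaries(text)
    starts = [0] + bounds
    ends = bounds + ([len(text)] if (not bounds or bounds[-1] < len(text)) else [])
    sentences: list[Sentence] = []
    for s, e in zip(starts, ends):
        chunk = text[s:e]
        ls = len(chunk) - len(chunk.lstrip())
        le = len(chunk.rstrip())
        if le <= ls:
            continue
        sentences.append(Sentence((base + s + ls, base + s + le), section_name))
    return sentences


# ---------------------------------------------------------------------------
# Parsing


def parse_report(
    report_id: str,
    raw_text: str,
    aliases: dict[str, list[str]] | None = None,
    patient_id: str | None = None,
) -> ReportDocument:
    """Parse raw report text into a sectioned, sentence-segmented document.

    Text before the first recognised header (or the whole text when no header
    is found) becomes a single UNKNOWN section.  Raises
    :class:`ReportParseError` on empty input.
    """
    if not raw_text or not raw_text.strip():
        raise ReportParseError(f"report {report_id!r}: text is empty")
    if aliases is None:
        aliases = load_section_aliases()

    headers = _find_headers(raw_text, aliases)
    sections: list[Section] = []
    if not headers:
        sections.append(Section("UNKNOWN", (0, 0), (0, len(raw_text))))
    else:
        if headers[0][0] > 0:
            sections.append(Section("UNKNOWN", (0, 0), (0, headers[0][0])))
        for k, (hs, he, label) in enumerate(headers):
            body_end = headers[k + 1][0] if k + 1 < len(headers) else len(raw_text)
            sections.append(Section(label, (hs, he), (he, body_end)))

    sentences: list[Sentence] = []
    for sec in sections:
        b0, b1 = sec.body_span
        sentences.extend(_segment_body(raw_text[b0:b1], b0, sec.name))

    return ReportDocument(
        report_id=report_id,
        text=raw_text,
        patient_id=patient_id,
        sections=sections,
        sentences=sentences,
    )


# ---------------------------------------------------------------------------
# Corpus I/O


def read_corpus(
    path: str | Path,
    format: str = "jsonl",
    aliases: dict[str, list[str]] | None = None,
) -> list[ReportDocument]:
    """Read a corpus of reports, preserving input order.

    ``format`` is ``"jsonl"`` (one object per line with ``report_id``,
    optional ``patient_id`` and ``text``) or ``"textdir"`` (a directory of
    ``*.txt`` files whose stem is the report id).  Duplicate report ids are an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise ReportParseError(f"corpus path does not exist: {path}")
    if aliases is None:
        aliases = load_section_aliases()

    docs: list[ReportDocument] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ReportParseError(f"{path}:{lineno}: malformed JSON ({exc.msg})") from exc
                for key in ("report_id", "text"):
                    if key not in rec:
                        raise ReportParseError(f"{path}:{lineno}: missing required field {key!r}")
                docs.append(
                    parse_report(
                        str(rec["report_id"]),
                        rec["text"],
                        aliases=aliases,
                        patient_id=rec.get("patient_id"),
                    )
                )
    elif format == "textdir":
        if not path.is_dir():
            raise ReportParseError(f"not a directory: {path}")
        for fp in sorted(path.glob("*.txt")):
            docs.append(parse_report(fp.stem, fp.read_text(encoding="utf-8"), aliases=aliases))
    else:
        raise ReportParseError(f"unknown corpus format: {format!r}")

    seen: dict[str, int] = {}
    dupes = []
    for d in docs:
        seen[d.report_id] = seen.get(d.report_id, 0) + 1
    dupes = sorted(rid for rid, n in seen.items() if n > 1)
    if dupes:
        raise ReportParseError(f"duplicate report_ids in corpus: {', '.join(dupes)}")
    return docs


def write_corpus_jsonl(docs: list[ReportDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            rec = {"report_id": d.report_id, "text": d.text}
            if d.patient_id is not None:
                rec["patient_id"] = d.patient_id
            fh.write(json.dumps(rec) + "\n")
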