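"""Numbered-reference extraction: flatten, find marker spans, slice, parse.

PDF layout analysis fragments reference entries unpredictably — an entry
longer than one line often arrives as several blocks.  Rather than guessing
how fragments group, the whole reference section is flattened into one long
string; the printed sequence-number markers ("[1]", "[2]", ...) are then
located, the maximal run of consecutive numbers starting at 1 is accepted
(which rejects stray in-text bracket citations), and the string is sliced
between consecutive marker starts into entries.  Field parsing (authors,
journal, year, pages) is best-effort: the raw substring is the contract.

Author–year styles without printed sequence numbers are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .sections import SPACE_OCCUPIER, Section
from .templates import Template

__all__ = [
    "FlatReferenceString",
    "MarkerSpan",
    "ReferenceEntry",
    "flatten_reference_blocks",
    "find_marker_spans",
    "build_slicing_indexes",
    "slice_references",
    "parse_reference_entry",
    "extract_references",
]

_MARKER_PATTERNS = {
    # Span = match span of the marker pattern including one optional trailing
    # space (printed spans in running text slightly exceed the marker glyphs).
    "bracketed": re.compile(r"\[(\d{1,3})\] ?"),
    "dotted": re.compile(r"(?:(?<=\s)|^)(?<![\d.])(\d{1,3})\.(?=\s) ?"),
    "parenthesized": re.compile(r"\((\d{1,3})\) ?"),
}

_YEAR = re.compile(r"(?<!\d)(1[89]\d{2}|20\d{2})(?!\d)")
_PAGES = re.compile(r"\d+\s*[-–−‐]\s*\d+")


@dataclass(frozen=True)
class FlatReferenceString:
    """The reference section as one string, plus slot provenance."""

    text: str
    source_slots: tuple[int, ...] = ()


@dataclass(frozen=True)
class MarkerSpan:
    """Character extent of one sequence-number marker in the flat string."""

    sequence_number: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("marker span must be non-empty")


@dataclass
class ReferenceEntry:
    raw: str
    sequence_number: int
    authors: str | None = None
    journal: str | None = None
    year: int | None = None
    pages: str | None = None


def flatten_reference_blocks(section: Section | list[str],
                             slots_start: int = 0) -> FlatReferenceString:
    """Join the reference section's slots into a single long string.

    Occupier slots (removed noise) are skipped; single spaces join the
    fragments, so differently fragmented extractions of the same section
    flatten identically.
    """
    if isinstance(section, Section):
        slots, start = section.slots, section.start + 1
    else:
        slots, start = section, slots_start
    kept: list[str] = []
    provenance: list[int] = []
    for offset, slot in enumerate(slots):
        if slot == SPACE_OCCUPIER or not slot.strip():
            continue
        kept.append(" ".join(slot.split()))
        provenance.append(start + offset)
    return FlatReferenceString(" ".join(kept), tuple(provenance))


def find_marker_spans(
    flat: FlatReferenceString, template: Template
) -> list[MarkerSpan]:
    """All marker matches, filtered to the maximal consecutive run 1,2,3,...

    The consecutive-run constraint is what separates true entry markers from
    in-text bracket citations that survived into the reference section.  With
    no run starting at 1 the result is empty (unnumbered styles are not
    handled).
    """
    pattern = _MARKER_PATTERNS[template.reference_marker_style]
    matches = [
        (int(m.group(1)), m.start(), m.end()) for m in pattern.finditer(flat.text)
    ]
    best: list[tuple[int, int, int]] = []
    i = 0
    while i < len(matches):
        if matches[i][0] != 1:
            i += 1
            continue
        run = [matches[i]]
        j = i + 1
        while j < len(matches):
            if matches[j][0] == run[-1][0] + 1:
                run.append(matches[j])
            j += 1
        if len(run) > len(best):
            best = run
        i += 1
    return [MarkerSpan(n, s, e) for n, s, e in best]


def build_slicing_indexes(
    spans: list[MarkerSpan], flat_length: int
) -> list[tuple[int, int]]:
    """Entry i runs from the start of marker i to the start of marker i+1.

    The starting indexes, offset by one position against the ending indexes,
    become the slicing pairs; the final entry closes at the string end.
    """
    starts = [span.start for span in spans]
    return [
        (start, nxt)
        for start, nxt in zip(starts, starts[1:] + [flat_length])
    ]


def slice_references(
    flat: FlatReferenceString,
    index_pairs: list[tuple[int, int]],
    spans: list[MarkerSpan] | None = None,
) -> list[ReferenceEntry]:
    """Cut the flat string into raw entries, one per slicing pair."""
    entries: list[ReferenceEntry] = []
    for i, (start, end) in enumerate(index_pairs):
        if not 0 <= start < end <= len(flat.text):
            raise ValueError(f"slicing pair ({start}, {end}) out of bounds")
        number = spans[i].sequence_number if spans else i + 1
        entries.append(ReferenceEntry(raw=flat.text[start:end].strip(), sequence_number=number))
    return entries


def parse_reference_entry(entry: ReferenceEntry, template: Template | None = None) -> ReferenceEntry:
    """Best-effort field parsing; unparsed fields stay absent, raw is kept.

    Year is the first in-range 4-digit token; pages the last "first–last"
    digit pair; the text before the year splits on commas into authors (all
    but the last chunk) and journal (the last chunk).
    """
    style = template.reference_marker_style if template else "bracketed"
    body = _MARKER_PATTERNS[style].sub("", entry.raw, count=1).strip()
    year_match = _YEAR.search(body)
    year = int(year_match.group(0)) if year_match else None
    pages_matches = _PAGES.findall(body)
    pages = re.sub(r"\s+", "", pages_matches[-1]) if pages_matches else None
    authors = journal = None
    if year_match:
        head = body[: year_match.start()].strip(" ,")
        chunks = [c.strip() for c in head.split(", ") if c.strip()]
        if len(chunks) >= 2:
            authors = ", ".join(chunks[:-1])
            journal = chunks[-1]
        elif chunks:
            journal = chunks[0]
    return replace(entry, authors=authors, journal=journal, year=year, pages=pages)


def extract_references(
    section: Section, template: Template
) -> list[ReferenceEntry]:
    """Full reference stage: flatten, locate markers, slice, parse."""
    flat = flatten_reference_blocks(section)
    spans = find_marker_spans(flat, template)
    pairs = build_slicing_indexes(spans, len(flat.text))
    entries = slice_references(flat, pairs, spans)
    return [parse_reference_entry(e, template) for e in entries]
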