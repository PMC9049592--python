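"""Front-matter metadata extraction from first-page text blocks.

Title, abstract, keywords, DOI, journal line, authors and emails live on the
first page of a typeset article; captions are scattered through the whole
document.  Every extractor here is a rule pipeline parameterized by the active
:class:`~paperblocks.templates.Template` and reports, besides its value, the
universal sequence numbers of the blocks it consumed — the orchestrator feeds
only unclaimed blocks to section detection.

Abstract layouts come in three flavours:

1. one block carrying both the "Abstract" label and the abstract body;
2. a short standalone "Abstract" label block with the body in a separate,
   vertically aligned block below it;
3. no "abstract" string at all — the abstract is taken as the largest-area
   qualifying first-page block, with post-extraction filtration so an
   "Introduction" passage is not mistaken for it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .blocks import TextBlock, normalize_text
from .templates import Template

__all__ = [
    "CaptionEntry",
    "MetadataRecord",
    "extract_abstract",
    "extract_title",
    "extract_keywords",
    "extract_captions",
    "extract_front_matter",
    "extract_metadata",
]

_TITLE_FONT_TOLERANCE = 0.1   # pt; per-character filter inside the title block
_EMAIL_PATTERN = re.compile(r"[A-Za-z0-9._%+-]+@[A-Za-z0-9.-]+\.[A-Za-z]{2,}")
_NUMBERED_HEADING = re.compile(r"^\d+(\.\d+)*\.?\s+\S")
_INTRO_HEADING = re.compile(r"^\s*\d*\.?\s*introduction\s*$", re.IGNORECASE)
_AFFILIATION_MARKERS = re.compile(
    r"@|†|‡|§|\b(university|laboratory|institute|department|corresponding)\b",
    re.IGNORECASE,
)
_JOURNAL_LINE = re.compile(
    r"^(?P<name>\D{3,}?)[\s,]+(?P<year>1[89]\d{2}|20\d{2}),\s*"
    r"(?P<volume>\d+)\s*(?:\((?P<issue>\d+)\))?\s*,\s*"
    r"(?P<pages>\d+\s*[-–−‐]\s*\d+)"
)


@dataclass(frozen=True)
class CaptionEntry:
    label_kind: str          # figure | table | scheme
    sequence_number: int
    text: str

    def __post_init__(self) -> None:
        if self.sequence_number < 1:
            raise ValueError("caption sequence numbers start at 1")


@dataclass
class MetadataRecord:
    """Structured front matter; ``None`` means absent, never empty."""

    title: str | None = None
    abstract: str | None = None
    abstract_case: int | None = None
    doi: str | None = None
    journal_name: str | None = None
    year: int | None = None
    volume: str | None = None
    issue: str | None = None
    page_range: str | None = None
    keywords: list[str] = field(default_factory=list)
    authors: list[str] = field(default_factory=list)
    emails: list[str] = field(default_factory=list)
    captions: list[CaptionEntry] = field(default_factory=list)


def _norm(text: str) -> str:
    return " ".join(normalize_text(text).split())


def _is_abstract_label(block: TextBlock) -> bool:
    bare = re.sub(r"[^a-z]", "", block.text.lower())
    return bare == "abstract"


def _x_aligned(a: TextBlock, b: TextBlock, tolerance: float) -> bool:
    """Alignment = x-interval overlap ratio >= 0.9 OR left edges within tolerance."""
    overlap = min(a.bbox.x1, b.bbox.x1) - max(a.bbox.x0, b.bbox.x0)
    narrower = min(a.bbox.width, b.bbox.width)
    if narrower > 0 and overlap / narrower >= 0.9:
        return True
    return abs(a.bbox.x0 - b.bbox.x0) <= tolerance


def extract_abstract(
    first_page_blocks: list[TextBlock], template: Template
) -> tuple[str | None, int | None, set[int]]:
    """Return (abstract text, case tag 1|2|3, claimed universal sequences)."""
    blocks = [b for b in first_page_blocks if not b.is_blank]

    # Case 1: label embedded in the abstract block itself.
    for block in blocks:
        if (
            "abstract" in block.text.lower()
            and block.number_of_word >= template.abstract_min_words
        ):
            text = re.sub(r"^\s*abstract\s*[:.\-–—]*\s*", "", _norm(block.text),
                          flags=re.IGNORECASE)
            return text, 1, {block.universal_sequence}

    # Case 2: standalone "Abstract" identifier; body vertically aligned below.
    identifier = next((b for b in blocks if _is_abstract_label(b)), None)
    if identifier is not None:
        for block in blocks:
            if block.universal_sequence <= identifier.universal_sequence:
                continue
            below = block.bbox.y1 <= identifier.bbox.y0 + 1.0
            if below and _x_aligned(identifier, block, template.abstract_align_tolerance):
                return (
                    _norm(block.text),
                    2,
                    {identifier.universal_sequence, block.universal_sequence},
                )
        return None, 2, {identifier.universal_sequence}

    # Case 3: no "abstract" string anywhere — largest-area qualifying block,
    # with filtration so a first-page Introduction passage loses out.
    by_useq = {b.universal_sequence: b for b in blocks}
    candidates = [
        b
        for b in blocks
        if b.number_of_word >= template.abstract_min_words
        and not _NUMBERED_HEADING.match(b.text.strip())
    ]
    for block in sorted(candidates, key=lambda b: b.bbox.area, reverse=True):
        preceding = by_useq.get(block.universal_sequence - 1)
        if preceding is not None and _INTRO_HEADING.match(preceding.text.strip()):
            continue  # that's the introduction body, not the abstract
        return _norm(block.text), 3, {block.universal_sequence}
    return None, None, set()


def extract_title(
    first_page_blocks: list[TextBlock], template: Template
) -> tuple[str | None, set[int]]:
    """Centered, length-bounded, maximal-font block; then per-character filter.

    Within the winning block only characters within 0.1 pt of the block's
    maximal character size survive — this strips merged small-font noise such
    as article-type banners or author lines glued onto the title block.
    """
    lo, hi = template.title_word_range
    candidates = [
        b
        for b in first_page_blocks
        if not b.is_blank
        and b.center_offset is not None
        and b.center_offset <= template.title_center_tolerance
        and lo <= b.number_of_word <= hi
    ]
    if not candidates:
        return None, set()
    winner = max(candidates, key=lambda b: (b.dominant_font_size or 0.0))
    max_size = max(winner.chars.font_sizes)
    kept = [
        ch
        for ch, size in zip(winner.chars.text, winner.chars.font_sizes)
        if size >= max_size - _TITLE_FONT_TOLERANCE
    ]
    title = " ".join("".join(kept).split())
    return (title or None), {winner.universal_sequence}


def extract_keywords(
    first_page_blocks: list[TextBlock], template: Template
) -> tuple[list[str], set[int]]:
    """First block carrying the keyword label; split on ';' else ','."""
    label = re.compile(template.keyword_label, re.IGNORECASE)
    for block in first_page_blocks:
        match = label.search(block.text)
        if not match:
            continue
        tail = _norm(block.text[match.end():]).lstrip(":.-–— ")
        for sep in (";", ","):
            parts = [p.strip(" .;,") for p in tail.split(sep)]
            parts = [p for p in parts if p]
            if len(parts) >= 2:
                return parts, {block.universal_sequence}
        return ([tail] if tail else []), {block.universal_sequence}
    return [], set()


_KIND_MAP = {"figure": "figure", "fig": "figure", "fig.": "figure",
             "table": "table", "scheme": "scheme"}


def extract_captions(
    all_blocks: list[TextBlock], template: Template
) -> tuple[list[CaptionEntry], set[int]]:
    """Blocks starting with "Figure N" / "Table N" / "Scheme N".

    The label prefix stays in the caption text; entries are sorted by
    (kind, sequence number).
    """
    pattern = re.compile(template.caption_labels)
    entries: list[tuple[CaptionEntry, int]] = []
    for block in all_blocks:
        match = pattern.match(block.text.strip())
        if not match:
            continue
        kind = _KIND_MAP.get(match.group(1).lower(), match.group(1).lower())
        entries.append(
            (
                CaptionEntry(kind, int(match.group(2)), _norm(block.text)),
                block.universal_sequence,
            )
        )
    entries.sort(key=lambda pair: (pair[0].label_kind, pair[0].sequence_number))
    return [e for e, _ in entries], {u for _, u in entries}


@dataclass
class FrontMatter:
    doi: str | None = None
    journal_name: str | None = None
    year: int | None = None
    volume: str | None = None
    issue: str | None = None
    page_range: str | None = None
    authors: list[str] = field(default_factory=list)
    emails: list[str] = field(default_factory=list)
    claimed: set[int] = field(default_factory=set)


def extract_front_matter(
    first_page_blocks: list[TextBlock],
    template: Template,
    title_useq: int | None = None,
    abstract_useqs: set[int] | None = None,
) -> FrontMatter:
    """DOI, journal line, authors and emails; each field independently optional."""
    result = FrontMatter()
    abstract_useqs = abstract_useqs or set()
    doi_pattern = re.compile(template.doi_pattern)

    for block in first_page_blocks:
        match = doi_pattern.search(block.text)
        if match:
            result.doi = match.group(0).rstrip(".,;:)]}")
            result.claimed.add(block.universal_sequence)
            break

    for block in first_page_blocks:
        for email in _EMAIL_PATTERN.findall(block.text):
            if email not in result.emails:
                result.emails.append(email)
                result.claimed.add(block.universal_sequence)

    # Journal line: topmost block shaped like "name year, volume, first−last".
    for block in first_page_blocks:
        match = _JOURNAL_LINE.match(_norm(block.text))
        if match and block.universal_sequence not in abstract_useqs:
            result.journal_name = match.group("name").strip(" ,")
            result.year = int(match.group("year"))
            result.volume = match.group("volume")
            result.issue = match.group("issue")
            result.page_range = re.sub(r"\s+", "", match.group("pages"))
            result.claimed.add(block.universal_sequence)
            break

    # Authors: positional sandwich between the title and the abstract region,
    # smaller font than the title, not an affiliation/journal/DOI/email block.
    if title_useq is not None:
        stop = min(abstract_useqs) if abstract_useqs else None
        title_block = next(
            b for b in first_page_blocks if b.universal_sequence == title_useq
        )
        for block in first_page_blocks:
            useq = block.universal_sequence
            if useq <= title_useq or (stop is not None and useq >= stop):
                continue
            if block.is_blank or useq in result.claimed:
                continue
            if (block.dominant_font_size or 0) >= (title_block.dominant_font_size or 0):
                continue
            if _AFFILIATION_MARKERS.search(block.text):
                continue
            tokens = [
                t.strip(" .;")
                for t in re.split(r",\s*|\s+\band\b\s+", _norm(block.text))
            ]
            tokens = [t for t in tokens if t and not t.isdigit()]
            if tokens:
                result.authors = tokens
                result.claimed.add(useq)
                break
    return result


def extract_metadata(model, template: Template) -> tuple[MetadataRecord, set[int]]:
    """Run every metadata extractor; return the record and all claimed blocks."""
    first_page = model.page_blocks(0)
    record = MetadataRecord()
    claimed: set[int] = set()

    title, title_useqs = extract_title(first_page, template)
    record.title = title
    claimed |= title_useqs

    abstract, case, abstract_useqs = extract_abstract(first_page, template)
    record.abstract, record.abstract_case = abstract, case
    claimed |= abstract_useqs

    keywords, kw_useqs = extract_keywords(first_page, template)
    record.keywords = keywords
    claimed |= kw_useqs

    captions, caption_useqs = extract_captions(list(model.blocks), template)
    record.captions = captions
    claimed |= caption_useqs

    front = extract_front_matter(
        first_page,
        template,
        title_useq=next(iter(title_useqs), None),
        abstract_useqs=abstract_useqs,
    )
    record.doi = front.doi
    record.journal_name = front.journal_name
    record.year = front.year
    record.volume = front.volume
    record.issue = front.issue
    record.page_range = front.page_range
    record.authors = front.authors
    record.emails = front.emails
    claimed |= front.claimed
    return record, claimed
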