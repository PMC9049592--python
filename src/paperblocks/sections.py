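"""Noise detection, heading location, and main-body segmentation.

The stage has two halves.  *Noise-search-pattern creation* finds per-page
furniture — running headers repeat near the top of every page, page numbers
are lone short numerals — by screening the first ``noise_block_count`` blocks
of each page against a compare-list seeded from page one and updated until the
final page; confirmed repeats are escaped into search patterns, and page-number
and caption patterns are appended.

*Main-body segmentation* walks every block in universal-sequence order: a
noise hit contributes a space-occupier sentinel (so the body list keeps one
slot per universal sequence number), anything else contributes its text.
Heading candidates are collected into three parallel lists — location, string,
font — cleaned by the largest-font rule (true headings share the maximal font
size; smaller-font impostors are dropped), chained into half-open location
pairs, and used to slice the body list into named sections.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .blocks import DocumentModel, TextBlock
from .similarity import gestalt_similarity
from .templates import Template

__all__ = [
    "SPACE_OCCUPIER",
    "NoisePatternSet",
    "HeadingCandidates",
    "LocationPair",
    "Section",
    "SectionedBody",
    "FRONT_MATTER_TITLE",
    "WHOLE_DOCUMENT_TITLE",
    "build_noise_patterns",
    "collect_heading_candidates",
    "clean_candidates",
    "build_location_pairs",
    "build_body_list",
    "segment_body",
    "is_reference_title",
]

#: Sentinel occupying the body-list slot of a removed noise block.  A reserved
#: zero-width token: never emitted into any section text.
SPACE_OCCUPIER = "\u200b"

FRONT_MATTER_TITLE = "<front-matter>"
WHOLE_DOCUMENT_TITLE = "<document>"

_NOISE_SIMILARITY = 0.9       # digit-stripped repeat threshold across pages
_FONT_CLEAN_TOLERANCE = 0.05  # pt; ties at the max are all retained
_HEADING_FONT_EPSILON = 0.25  # pt; "larger than body font" margin

_NUMBERED_HEADING = re.compile(r"^\d+(\.\d+)*\.?\s+\S")
_PAGE_NUMBER = re.compile(r"^\s*(page\s+)?\d{1,4}\s*$", re.IGNORECASE)
_REFERENCE_TITLE = re.compile(
    r"^\s*\d*\.?\s*(references?|bibliography|literature\s+cited)\s*$", re.IGNORECASE
)


@dataclass
class NoisePatternSet:
    """Compiled patterns for headers, page numbers and captions."""

    header_patterns: list[re.Pattern] = field(default_factory=list)
    page_number_pattern: re.Pattern = _PAGE_NUMBER
    caption_pattern: re.Pattern | None = None

    def matches(self, text: str) -> bool:
        stripped = " ".join(text.split())
        if self.page_number_pattern.fullmatch(stripped):
            return True
        if self.caption_pattern is not None and self.caption_pattern.match(stripped):
            return True
        return any(p.fullmatch(stripped) for p in self.header_patterns)


@dataclass
class HeadingCandidates:
    """Three parallel lists: block location, heading text, heading font size."""

    location: list[int] = field(default_factory=list)
    string: list[str] = field(default_factory=list)
    font: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.location) == len(self.string) == len(self.font)):
            raise ValueError("location/string/font lists must stay parallel")
        if any(b <= a for a, b in zip(self.location, self.location[1:])):
            raise ValueError("location list must be strictly increasing")

    def append(self, location: int, string: str, font: float) -> None:
        if self.location and location <= self.location[-1]:
            raise ValueError("locations must be appended in increasing order")
        self.location.append(location)
        self.string.append(string)
        self.font.append(font)

    def __len__(self) -> int:
        return len(self.location)


@dataclass(frozen=True)
class LocationPair:
    """Half-open [start, end) span over universal sequence numbers."""

    start: int
    end: int
    title: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty location pair ({self.start}, {self.end})")


@dataclass
class Section:
    title: str
    start: int
    end: int
    slots: list[str]   # body-list slots inside the span, heading slot excluded
    text: str


@dataclass
class SectionedBody:
    front_matter: str
    sections: list[Section]

    def as_mapping(self) -> dict[str, str]:
        return {s.title: s.text for s in self.sections}


def _strip_digits(text: str) -> str:
    return re.sub(r"\d+", "", text)


def _header_pattern(text: str) -> re.Pattern:
    """Escape a confirmed header into a search pattern.

    Special characters (space, period, parentheses, ...) are escaped; digit
    runs generalize to ``\\d+`` so "Page 3" and "Page 12" unify; whitespace
    runs are flexible.
    """
    normalized = " ".join(text.split())
    parts = []
    for piece in re.split(r"(\d+|\s+)", normalized):
        if not piece:
            continue
        if piece.isdigit():
            parts.append(r"\d+")
        elif piece.isspace():
            parts.append(r"\s+")
        else:
            parts.append(re.escape(piece))
    return re.compile("".join(parts))


def build_noise_patterns(model: DocumentModel, template: Template) -> NoisePatternSet:
    """Induce header patterns from cross-page repetition among leading blocks.

    Page one's first ``noise_block_count`` block texts seed the compare-list;
    each later page's leading blocks are measured against it (similarity >= 0.9
    on digit-stripped text, so page-numbered variants of the same header
    unify), matches join the header-list, and the compare-list keeps growing
    until the final page.  With a single page only the page-number and caption
    patterns are produced.
    """
    n = template.noise_block_count
    result = NoisePatternSet(
        caption_pattern=re.compile(template.caption_labels, re.IGNORECASE)
    )
    if model.n_pages >= 2:
        pages = [model.page_blocks(i) for i in range(model.n_pages)]
        compare: list[str] = [
            " ".join(b.text.split()) for b in pages[0][:n] if not b.is_blank
        ]
        headers: list[str] = []
        for page in pages[1:]:
            texts = [" ".join(b.text.split()) for b in page[:n] if not b.is_blank]
            for text in texts:
                probe = _strip_digits(text)
                if not probe.strip():
                    continue
                for candidate in compare:
                    score = gestalt_similarity(probe, _strip_digits(candidate))
                    if score.dro >= _NOISE_SIMILARITY:
                        headers.append(text)
                        break
            compare.extend(texts)
        seen: set[str] = set()
        for header in headers:
            key = _strip_digits(header)
            if key in seen:
                continue
            seen.add(key)
            pattern = _header_pattern(header)
            # Repetition across pages is what defines furniture: confirm the
            # pattern only if it hits leading blocks on >= 2 distinct pages,
            # which rejects one-off body text that merely resembles a header.
            hit_pages = sum(
                1
                for page in pages
                if any(
                    pattern.fullmatch(" ".join(b.text.split()))
                    for b in page[:n]
                    if not b.is_blank
                )
            )
            if hit_pages >= 2:
                result.header_patterns.append(pattern)
    return result


def _is_heading(block: TextBlock, template: Template, body_font: float | None) -> bool:
    text = " ".join(block.text.split())
    if not text:
        return False
    for rule in template.heading_rules:
        if rule == "numbered":
            if _NUMBERED_HEADING.match(text) and block.number_of_word <= 12:
                return True
        elif rule == "unnumbered" and template.heading_uses_font:
            if (
                block.number_of_word <= 6
                and not text.endswith(".")
                and body_font is not None
                and (block.dominant_font_size or 0) > body_font + _HEADING_FONT_EPSILON
            ):
                return True
    return False


def collect_heading_candidates(
    model: DocumentModel,
    template: Template,
    exclude: set[int] | None = None,
) -> HeadingCandidates:
    """Scan blocks for section-title candidates using the template's rules.

    ``exclude`` carries universal sequence numbers already claimed as metadata
    (title, abstract, captions, ...) — the orchestrator only feeds
    section detection what metadata extraction left behind.  Caption-shaped
    and lone-page-number blocks are never candidates.
    """
    exclude = exclude or set()
    body_font = model.modal_font_size()
    caption = re.compile(template.caption_labels, re.IGNORECASE)
    candidates = HeadingCandidates()
    for block in model.blocks:
        if block.universal_sequence in exclude or block.is_blank:
            continue
        text = " ".join(block.text.split())
        if caption.match(text) or _PAGE_NUMBER.fullmatch(text):
            continue
        if _is_heading(block, template, body_font):
            candidates.append(
                block.universal_sequence, text, block.dominant_font_size or 0.0
            )
    return candidates


def clean_candidates(candidates: HeadingCandidates) -> HeadingCandidates:
    """Largest-font cleaning: true headings share the maximal font size.

    The maximum of the font list is computed; exactly the indexes whose font
    size lies within 0.05 pt of it are retained, and the location and string
    lists are filtered by those same indexes.
    """
    if not len(candidates):
        return HeadingCandidates()
    max_font = max(candidates.font)
    keep = [
        i
        for i, size in enumerate(candidates.font)
        if abs(size - max_font) <= _FONT_CLEAN_TOLERANCE
    ]
    return HeadingCandidates(
        location=[candidates.location[i] for i in keep],
        string=[candidates.string[i] for i in keep],
        font=[candidates.font[i] for i in keep],
    )


def build_location_pairs(
    cleaned: HeadingCandidates, total_blocks: int
) -> list[LocationPair]:
    """Chain heading locations into half-open section spans.

    Each heading location becomes the end of one pair and the start of the
    next; a leading pair from the document start captures front matter and the
    final pair is closed at ``total_blocks``.  With no headings at all, a
    single whole-document pair with a sentinel title is returned.
    """
    if not len(cleaned):
        if total_blocks <= 0:
            return []
        return [LocationPair(0, total_blocks, WHOLE_DOCUMENT_TITLE)]
    locations = cleaned.location
    if locations[-1] >= total_blocks:
        raise ValueError("heading location beyond document length")
    pairs: list[LocationPair] = []
    if locations[0] > 0:
        pairs.append(LocationPair(0, locations[0], FRONT_MATTER_TITLE))
    bounds = list(locations) + [total_blocks]
    for i, title in enumerate(cleaned.string):
        pairs.append(LocationPair(bounds[i], bounds[i + 1], title))
    return pairs


def build_body_list(model: DocumentModel, noise: NoisePatternSet) -> list[str]:
    """One slot per universal sequence number: block text, or the occupier.

    The total number of slots must stay equal to the block count so location
    pairs keep indexing correctly.
    """
    body: list[str] = []
    for block in model.blocks:
        if block.is_blank or noise.matches(block.text):
            body.append(SPACE_OCCUPIER)
        else:
            body.append(" ".join(block.text.split()))
    return body


def segment_body(body_list: list[str], pairs: list[LocationPair]) -> SectionedBody:
    """Slice the body list by location pairs into named sections.

    Section text joins the span's non-occupier slots with single spaces; the
    heading block at the start of each span titles the section and is excluded
    from its text.
    """
    if pairs and max(p.end for p in pairs) > len(body_list):
        raise ValueError("location pair exceeds body list length (inconsistent indexing)")
    front = ""
    sections: list[Section] = []
    for pair in pairs:
        if pair.title == FRONT_MATTER_TITLE:
            slots = body_list[pair.start : pair.end]
            front = " ".join(s for s in slots if s != SPACE_OCCUPIER)
            continue
        skip_heading = 1 if pair.title != WHOLE_DOCUMENT_TITLE else 0
        slots = body_list[pair.start + skip_heading : pair.end]
        text = " ".join(s for s in slots if s != SPACE_OCCUPIER)
        sections.append(Section(pair.title, pair.start, pair.end, slots, text))
    return SectionedBody(front_matter=front, sections=sections)


def is_reference_title(title: str) -> bool:
    """True when a section title names the bibliography."""
    return bool(_REFERENCE_TITLE.match(title))
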