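"""Backend-agnostic text-block data model.

A PDF layout backend (or the synthetic fixture generator) delivers, page by
page, positioned text blocks with per-character font sizes.  This module turns
that stream into a :class:`DocumentModel`: every block gets a *universal
sequence number* — a document-level index running 0, 1, 2, ... in reading
order, as if all pages were flattened into one — plus the per-block features
(word count, dominant font size, centeredness) that every later extraction
stage consumes.

The on-disk interchange is a plain JSON "block stream"::

    {"pages": [{"width": 612.0, "height": 792.0}, ...],
     "blocks": [{"page": 0, "index": 0, "useq": 0,
                 "bbox": [x0, y0, x1, y1],
                 "text": "...", "font_sizes": [10.0, ...]}, ...]}
"""

from __future__ import annotations

import json
import unicodedata
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "BoundingBox",
    "CharSpan",
    "TextBlock",
    "PageGeometry",
    "DocumentModel",
    "NoTextLayerError",
    "BlockStreamError",
    "normalize_text",
    "count_words",
    "build_document_model",
    "compute_block_features",
    "read_block_stream",
    "write_block_stream",
]

# Latin ligatures expanded before word counting so token counts are stable
# across publisher encodings.
_LIGATURES = {
    "ﬀ": "ff",
    "ﬁ": "fi",
    "ﬂ": "fl",
    "ﬃ": "ffi",
    "ﬄ": "ffl",
    "ﬅ": "st",
    "ﬆ": "st",
}


class NoTextLayerError(ValueError):
    """The document contains no text on any page (likely an image-based PDF)."""


class BlockStreamError(ValueError):
    """A block-stream JSON document violates the interchange schema."""


def normalize_text(text: str) -> str:
    """NFC-normalize and expand Latin ligatures."""
    text = unicodedata.normalize("NFC", text)
    for lig, exp in _LIGATURES.items():
        if lig in text:
            text = text.replace(lig, exp)
    return text


def count_words(text: str) -> int:
    """Whitespace-delimited token count after normalization."""
    return len(normalize_text(text).split())


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in PDF points, origin bottom-left, y increasing upward."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError(f"degenerate bbox: {(self.x0, self.y0, self.x1, self.y1)}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def x_center(self) -> float:
        return (self.x0 + self.x1) / 2.0


@dataclass(frozen=True)
class CharSpan:
    """Character string with a parallel per-character font-size sequence."""

    text: str
    font_sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.font_sizes) != len(self.text):
            raise ValueError(
                f"font_sizes length {len(self.font_sizes)} != text length {len(self.text)}"
            )


@dataclass(frozen=True)
class PageGeometry:
    width: float
    height: float


@dataclass(frozen=True)
class TextBlock:
    """One positioned text block — the atomic unit of the whole pipeline."""

    page_index: int
    in_page_index: int
    universal_sequence: int
    bbox: BoundingBox
    chars: CharSpan
    number_of_word: int = 0
    dominant_font_size: float | None = None
    center_offset: float | None = None

    @property
    def text(self) -> str:
        return self.chars.text

    @property
    def is_blank(self) -> bool:
        return not self.chars.text.strip()

    @property
    def key(self) -> tuple[int, int]:
        return (self.page_index, self.in_page_index)


@dataclass
class DocumentModel:
    """Ordered block collection plus per-page geometry."""

    pages: list[PageGeometry]
    blocks: list[TextBlock]
    _by_key: dict[tuple[int, int], TextBlock] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self._by_key = {}
        for expected, block in enumerate(self.blocks):
            if block.universal_sequence != expected:
                raise ValueError(
                    "universal_sequence must run 0,1,2,... in block order; "
                    f"got {block.universal_sequence} at position {expected}"
                )
            if block.key in self._by_key:
                raise ValueError(f"duplicate block key {block.key}")
            self._by_key[block.key] = block

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def __getitem__(self, key: tuple[int, int]) -> TextBlock:
        return self._by_key[key]

    def page_blocks(self, page_index: int) -> list[TextBlock]:
        return [b for b in self.blocks if b.page_index == page_index]

    @property
    def n_pages(self) -> int:
        return len(self.pages)

    def text(self) -> str:
        """Concatenation of all block texts in universal-sequence order."""
        return "".join(b.text for b in self.blocks)

    def modal_font_size(self) -> float | None:
        """Character-weighted modal font size over the whole document.

        This estimates the body-text size; headings and titles are rare
        relative to body characters.  Ties resolve to the smaller size (body
        text, not display text).
        """
        counts: Counter[float] = Counter()
        for block in self.blocks:
            counts.update(block.chars.font_sizes)
        if not counts:
            return None
        best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
        return best[0]


def compute_block_features(block: TextBlock, page: PageGeometry) -> TextBlock:
    """Populate derived per-block features (word count, dominant font, centering).

    ``dominant_font_size`` is the modal per-character size; ties resolve to the
    largest tied mode so title/heading glyphs win over superscripts.  A block
    with no characters keeps ``dominant_font_size`` as ``None``.
    """
    nwords = count_words(block.chars.text)
    dominant: float | None = None
    if block.chars.font_sizes:
        counts = Counter(block.chars.font_sizes)
        dominant = max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
    offset = abs(block.bbox.x_center - page.width / 2.0)
    return replace(
        block,
        number_of_word=nwords,
        dominant_font_size=dominant,
        center_offset=offset,
    )


def build_document_model(parsed_layout: Iterable[Mapping]) -> DocumentModel:
    """Assemble a :class:`DocumentModel` from a backend page stream.

    Parameters
    ----------
    parsed_layout
        Iterable of pages; each page is a mapping with ``width``, ``height``
        and ``blocks`` — an ordered sequence of mappings carrying ``text``,
        ``font_sizes`` and ``bbox`` ``(x0, y0, x1, y1)``.  Block order within
        a page is the backend's reading order and is preserved.

    Raises
    ------
    NoTextLayerError
        If no page contributes any non-empty text (image-based PDF).
    """
    pages: list[PageGeometry] = []
    blocks: list[TextBlock] = []
    useq = 0
    for page_index, page in enumerate(parsed_layout):
        geom = PageGeometry(float(page["width"]), float(page["height"]))
        pages.append(geom)
        for in_page_index, raw in enumerate(page["blocks"]):
            text = normalize_text(str(raw["text"]))
            sizes = tuple(float(s) for s in raw["font_sizes"])
            if len(sizes) != len(text):
                # Normalization (ligature expansion) may lengthen the text;
                # stretch the affected sizes by repeating the ligature's size.
                sizes = _renormalize_sizes(str(raw["text"]), raw["font_sizes"])
            block = TextBlock(
                page_index=page_index,
                in_page_index=in_page_index,
                universal_sequence=useq,
                bbox=BoundingBox(*(float(v) for v in raw["bbox"])),
                chars=CharSpan(text, sizes),
            )
            blocks.append(compute_block_features(block, geom))
            useq += 1
    if not any(not b.is_blank for b in blocks):
        raise NoTextLayerError("document has no text layer on any page")
    return DocumentModel(pages=pages, blocks=blocks)


def _renormalize_sizes(raw_text: str, raw_sizes: Sequence[float]) -> tuple[float, ...]:
    """Re-expand per-character sizes in step with ligature expansion."""
    out: list[float] = []
    for ch, size in zip(unicodedata.normalize("NFC", raw_text), raw_sizes):
        expansion = _LIGATURES.get(ch, ch)
        out.extend([float(size)] * len(expansion))
    return tuple(out)


# ---------------------------------------------------------------------------
# Block-stream JSON interchange
# ---------------------------------------------------------------------------

def write_block_stream(model: DocumentModel, path: str | Path) -> None:
    payload = {
        "pages": [{"width": p.width, "height": p.height} for p in model.pages],
        "blocks": [
            {
                "page": b.page_index,
                "index": b.in_page_index,
                "useq": b.universal_sequence,
                "bbox": [b.bbox.x0, b.bbox.y0, b.bbox.x1, b.bbox.y1],
                "text": b.text,
                "font_sizes": list(b.chars.font_sizes),
            }
            for b in model.blocks
        ],
    }
    Path(path).write_text(json.dumps(payload, ensure_ascii=False, indent=1))


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise BlockStreamError(f"missing required field '{key}' in {where}")
    return mapping[key]


def read_block_stream(path: str | Path) -> DocumentModel:
    """Read the block-stream JSON interchange written by :func:`write_block_stream`.

    Schema violations raise :class:`BlockStreamError` naming the offending
    field; the resulting model satisfies all :class:`DocumentModel` invariants.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise BlockStreamError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise BlockStreamError("top-level document must be a JSON object")
    raw_pages = _require(payload, "pages", "document")
    raw_blocks = _require(payload, "blocks", "document")
    if not isinstance(raw_pages, list) or not isinstance(raw_blocks, list):
        raise BlockStreamError("'pages' and 'blocks' must be JSON arrays")

    pages = []
    for i, p in enumerate(raw_pages):
        pages.append(
            {
                "width": _require(p, "width", f"pages[{i}]"),
                "height": _require(p, "height", f"pages[{i}]"),
                "blocks": [],
            }
        )
    for i, b in enumerate(raw_blocks):
        where = f"blocks[{i}]"
        page = _require(b, "page", where)
        if not isinstance(page, int) or not 0 <= page < len(pages):
            raise BlockStreamError(f"field 'page' out of range in {where}")
        bbox = _require(b, "bbox", where)
        if not (isinstance(bbox, list) and len(bbox) == 4):
            raise BlockStreamError(f"field 'bbox' must be [x0,y0,x1,y1] in {where}")
        text = _require(b, "text", where)
        sizes = _require(b, "font_sizes", where)
        if len(sizes) != len(text):
            raise BlockStreamError(
                f"field 'font_sizes' length mismatch with 'text' in {where}"
            )
        pages[page]["blocks"].append({"text": text, "font_sizes": sizes, "bbox": bbox})
    try:
        return build_document_model(pages)
    except NoTextLayerError:
        raise
    except ValueError as exc:
        raise BlockStreamError(str(exc)) from exc
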