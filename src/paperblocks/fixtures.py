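"""Synthetic-article generation: block streams with golden ground truth.

Real publisher corpora are copyrighted and cannot ship with the package, so
every layout phenomenon the pipeline depends on is emulated here from a seeded
generator: a centered large-font title, an author line, an affiliation line
with an email, a journal line, a DOI, the three abstract layouts, numbered or
unnumbered section headings at a distinct font size, figure captions that form
separate blocks, repeated per-page running headers and page numbers, and a
numbered reference list whose entries fragment across multiple blocks.

Every generated article comes with its :class:`GoldenTruth` — the exact
strings a perfect extraction would return — so the whole pipeline is testable
without downloading a single article.  Generation is deterministic given the
spec's seed.

The generated prose is seeded pseudo-text from a fixed vocabulary.  It
emulates block-level layout, not language: single-column pages, clean reading
order, no tables, no formulae, no two-column flow.  Passing on fixtures
therefore demonstrates the block-level logic, not robustness to every real
publisher layout.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator

from .blocks import DocumentModel, build_document_model

__all__ = ["FixtureSpec", "GoldenTruth", "generate_article", "generate_corpus", "render_pdf"]

PAGE_WIDTH = 612.0
PAGE_HEIGHT = 792.0
_MARGIN = 57.0

_VOCABULARY = (
    "lattice thermal transport phonon carrier mobility perovskite film anneal "
    "precursor solvent ratio crystalline domain boundary defect density trap "
    "state recombination lifetime spectrum emission quantum yield substrate "
    "deposition vapor phase growth kinetics nucleation island coverage strain "
    "relaxation interface dipole alignment band offset barrier height doping "
    "profile gradient diffusion length minority majority conduction valence"
).split()

_SECTION_NAMES = (
    "Introduction",
    "Methods",
    "Results",
    "Discussion",
    "Conclusions",
    "Experimental",
    "Analysis",
    "Outlook",
)

_SURNAMES = (
    "Rivera", "Chen", "Novak", "Okafor", "Svensson", "Tanaka", "Moretti",
    "Haddad", "Kowalski", "Iyer",
)

_JOURNAL_NAMES = ("J. Synth. Rep.", "Ann. Block Anal.", "Lett. Doc. Sci.")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic article."""

    seed: int = 0
    n_pages: int = 4
    n_sections: int = 3
    n_refs: int = 5
    abstract_case: int = 1          # 1 | 2 | 3
    heading_style: str = "numbered"  # numbered | unnumbered
    header_text: str | None = None   # None -> derived from journal name + year
    fragment_refs: bool = True
    inject_noise: bool = True
    title_font: float = 18.0
    heading_font: float = 12.0
    body_font: float = 10.0

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.n_refs < 0:
            raise ValueError("n_refs must be >= 0")
        if self.abstract_case not in (1, 2, 3):
            raise ValueError("abstract_case must be 1, 2 or 3")
        if self.heading_style not in ("numbered", "unnumbered"):
            raise ValueError("heading_style must be 'numbered' or 'unnumbered'")
        if not self.title_font > self.heading_font > self.body_font:
            raise ValueError("fonts must satisfy title > heading > body")
        if self.n_pages < 3:
            raise ValueError("n_pages must be >= 3 (front page, body, references)")
        if self.n_sections > min(len(_SECTION_NAMES), 3 * (self.n_pages - 2)):
            raise ValueError("n_pages too small for n_sections")


@dataclass
class GoldenTruth:
    """Exact strings a perfect extraction of the fixture would return."""

    title: str = ""
    abstract: str = ""
    doi: str = ""
    journal: dict = field(default_factory=dict)
    keywords: list[str] = field(default_factory=list)
    authors: list[str] = field(default_factory=list)
    emails: list[str] = field(default_factory=list)
    sections: list[dict] = field(default_factory=list)
    captions: list[str] = field(default_factory=list)
    references: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "title": self.title,
            "abstract": self.abstract,
            "doi": self.doi,
            "journal": dict(self.journal),
            "keywords": list(self.keywords),
            "authors": list(self.authors),
            "emails": list(self.emails),
            "sections": [dict(s) for s in self.sections],
            "captions": list(self.captions),
            "references": list(self.references),
        }


def _prose(rng: random.Random, n_words: int) -> str:
    return " ".join(rng.choice(_VOCABULARY) for _ in range(n_words))


def _block(text: str, size: float, x0: float, y1: float, width: float,
           height: float) -> dict:
    return {
        "text": text,
        "font_sizes": [size] * len(text),
        "bbox": [x0, y1 - height, x0 + width, y1],
    }


def _centered_block(text: str, size: float, y1: float, width: float,
                    height: float) -> dict:
    return _block(text, size, PAGE_WIDTH / 2 - width / 2, y1, width, height)


class _PageBuilder:
    def __init__(self) -> None:
        self.pages: list[dict] = []

    def new_page(self) -> list[dict]:
        page = {"width": PAGE_WIDTH, "height": PAGE_HEIGHT, "blocks": []}
        self.pages.append(page)
        return page["blocks"]


def generate_article(spec: FixtureSpec) -> tuple[DocumentModel, GoldenTruth]:
    """Deterministically generate one article and its golden truth."""
    rng = random.Random(spec.seed)
    truth = GoldenTruth()
    builder = _PageBuilder()

    journal_name = rng.choice(_JOURNAL_NAMES)
    year = rng.randint(2012, 2024)
    volume = rng.randint(5, 60)
    page_start = rng.randint(100, 900)
    page_range = f"{page_start}−{page_start + rng.randint(5, 30)}"
    header = spec.header_text or f"{journal_name} {year}"
    doi = f"10.{rng.randint(1000, 9999)}/synth.{year}.{rng.randint(1000, 9999)}"

    title_words = [w.capitalize() for w in
                   (_prose(rng, rng.randint(5, 8)).split())]
    title = " ".join(title_words)
    truth.title = title

    n_authors = rng.randint(2, 4)
    surnames = rng.sample(_SURNAMES, n_authors)
    authors = [f"{chr(ord('A') + i)}. {s}" for i, s in enumerate(surnames)]
    truth.authors = authors
    email = f"{surnames[0].lower()}@example.org"
    truth.emails = [email]
    truth.doi = doi
    truth.journal = {
        "name": journal_name,
        "year": year,
        "volume": str(volume),
        "pages": page_range,
    }
    keywords = rng.sample(_VOCABULARY, rng.randint(3, 5))
    truth.keywords = keywords
    abstract_text = _prose(rng, 60)
    truth.abstract = abstract_text

    # ---- first page -------------------------------------------------------
    blocks = builder.new_page()
    y = PAGE_HEIGHT - 12
    if spec.inject_noise:
        blocks.append(_block(header, spec.body_font, _MARGIN, y, 180, 10))
        blocks.append(_block("1", spec.body_font, PAGE_WIDTH - 80, y, 12, 10))
        y -= 24
    blocks.append(_centered_block(title, spec.title_font, y, 420, 44))
    y -= 56
    author_line = ", ".join(authors[:-1]) + " and " + authors[-1] \
        if len(authors) > 1 else authors[0]
    blocks.append(_centered_block(author_line, spec.body_font, y, 300, 12))
    y -= 18
    blocks.append(
        _block(
            f"Department of Document Studies, University of Examples. "
            f"Correspondence: {email}",
            spec.body_font, _MARGIN, y, 430, 12,
        )
    )
    y -= 18
    blocks.append(
        _block(f"{journal_name} {year}, {volume}, {page_range}",
               spec.body_font, _MARGIN, y, 220, 11)
    )
    y -= 16
    blocks.append(_block(f"doi.org/{doi}", spec.body_font, _MARGIN, y, 200, 11))
    y -= 22

    if spec.abstract_case == 1:
        blocks.append(
            _block(f"Abstract {abstract_text}", spec.body_font, _MARGIN, y,
                   PAGE_WIDTH - 2 * _MARGIN, 120)
        )
        y -= 132
    elif spec.abstract_case == 2:
        blocks.append(_block("Abstract", spec.body_font, _MARGIN, y, 53, 12))
        y -= 18
        blocks.append(
            _block(abstract_text, spec.body_font, _MARGIN, y,
                   PAGE_WIDTH - 2 * _MARGIN, 120)
        )
        y -= 132
    else:
        # widest, tallest block on the page: largest area wins
        blocks.append(
            _block(abstract_text, spec.body_font, _MARGIN, y,
                   PAGE_WIDTH - 2 * _MARGIN, 150)
        )
        y -= 162
    blocks.append(
        _block("Keywords: " + "; ".join(keywords), spec.body_font, _MARGIN, y,
               380, 12)
    )

    # ---- body pages -------------------------------------------------------
    names = list(_SECTION_NAMES[: spec.n_sections])
    headings = (
        [f"{i + 1}. {name}" for i, name in enumerate(names)]
        if spec.heading_style == "numbered"
        else names
    )
    body_pages = spec.n_pages - 2
    per_page = -(-spec.n_sections // body_pages)  # ceil
    section_iter: Iterator[tuple[str, str]] = iter(zip(headings, names))
    caption_counter = 0
    done = 0
    for _ in range(body_pages):
        blocks = builder.new_page()
        y = PAGE_HEIGHT - 12
        if spec.inject_noise:
            page_no = len(builder.pages)
            blocks.append(_block(header, spec.body_font, _MARGIN, y, 180, 10))
            blocks.append(
                _block(str(page_no), spec.body_font, PAGE_WIDTH - 80, y, 12, 10)
            )
            y -= 24
        for heading, _name in _take(section_iter, min(per_page, spec.n_sections - done)):
            done += 1
            blocks.append(_block(heading, spec.heading_font, _MARGIN, y, 160, 14))
            y -= 22
            paragraphs = [_prose(rng, rng.randint(40, 60)) for _ in range(2)]
            for para in paragraphs:
                blocks.append(
                    _block(para, spec.body_font, _MARGIN, y,
                           PAGE_WIDTH - 2 * _MARGIN, 90)
                )
                y -= 100
            if rng.random() < 0.7:
                caption_counter += 1
                caption = (
                    f"Figure {caption_counter} " + _prose(rng, rng.randint(8, 14))
                )
                blocks.append(
                    _block(caption, spec.body_font, _MARGIN + 30, y, 400, 12)
                )
                truth.captions.append(caption)
                y -= 24
            truth.sections.append(
                {"title": heading, "text": " ".join(paragraphs)}
            )

    # ---- reference page ---------------------------------------------------
    blocks = builder.new_page()
    y = PAGE_HEIGHT - 12
    if spec.inject_noise:
        blocks.append(_block(header, spec.body_font, _MARGIN, y, 180, 10))
        blocks.append(
            _block(str(len(builder.pages)), spec.body_font, PAGE_WIDTH - 80, y, 12, 10)
        )
        y -= 24
    blocks.append(_block("References", spec.heading_font, _MARGIN, y, 120, 14))
    y -= 22
    for i in range(1, spec.n_refs + 1):
        n_ref_authors = rng.randint(1, 3)
        ref_authors = ", ".join(
            f"{chr(ord('D') + j)}. {rng.choice(_SURNAMES)}"
            for j in range(n_ref_authors)
        )
        ref_year = rng.randint(1995, 2024)
        ref_vol = rng.randint(1, 80)
        p0 = rng.randint(1, 2000)
        entry = (
            f"[{i}] {ref_authors}, {rng.choice(_JOURNAL_NAMES)} {ref_year}, "
            f"{ref_vol}, {p0}−{p0 + rng.randint(3, 40)}."
        )
        truth.references.append(entry)
        fragments = (
            _fragment(entry, rng) if spec.fragment_refs else [entry]
        )
        for fragment in fragments:
            blocks.append(
                _block(fragment, spec.body_font, _MARGIN, y,
                       PAGE_WIDTH - 2 * _MARGIN, 11)
            )
            y -= 14

    model = build_document_model(builder.pages)
    return model, truth


def _take(iterator: Iterator, n: int) -> list:
    return [item for _, item in zip(range(n), iterator)]


def _fragment(entry: str, rng: random.Random) -> list[str]:
    """Split an entry at word boundaries into 2-3 pieces (layout line breaks)."""
    words = entry.split()
    n_pieces = rng.randint(2, 3)
    if len(words) < n_pieces + 1:
        return [entry]
    cuts = sorted(rng.sample(range(1, len(words)), n_pieces - 1))
    pieces = []
    prev = 0
    for cut in cuts + [len(words)]:
        pieces.append(" ".join(words[prev:cut]))
        prev = cut
    return pieces


def generate_corpus(
    n: int, seed: int = 0
) -> list[tuple[FixtureSpec, DocumentModel, GoldenTruth]]:
    """A deterministic fixture set covering all abstract cases x heading styles.

    The 3 x 2 grid is walked cyclically, so any ``n >= 6`` covers every
    combination at least once.
    """
    if n < 6:
        raise ValueError("a corpus needs n >= 6 to span the case grid")
    out = []
    for i in range(n):
        spec = FixtureSpec(
            seed=seed * 100_003 + i,
            abstract_case=i % 3 + 1,
            heading_style="numbered" if (i // 3) % 2 == 0 else "unnumbered",
            n_sections=3 + i % 3,
            n_refs=4 + i % 4,
        )
        model, truth = generate_article(spec)
        out.append((spec, model, truth))
    return out


def render_pdf(model: DocumentModel, path) -> None:
    """Render a document model to a real PDF (requires the ``pdf`` extra).

    The round trip back through a layout backend preserves the text content;
    geometry may shift within rendering tolerance.
    """
    if not len(model):
        raise ValueError("refusing to render an empty document model")
    try:
        from reportlab.pdfgen import canvas as rl_canvas
    except ImportError as exc:  # pragma: no cover - exercised only with extras
        raise MissingDependencyError(
            "render_pdf requires reportlab (install the 'pdf' extra)"
        ) from exc
    canv = rl_canvas.Canvas(str(path), pagesize=(PAGE_WIDTH, PAGE_HEIGHT))
    for page_index in range(model.n_pages):
        for block in model.page_blocks(page_index):
            size = block.dominant_font_size or 10.0
            text = canv.beginText(block.bbox.x0, block.bbox.y1 - size)
            text.setFont("Helvetica", size)
            text.textLine(block.text)
            canv.drawText(text)
        canv.showPage()
    canv.save()


class MissingDependencyError(ImportError):
    """An optional PDF dependency is not installed."""
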