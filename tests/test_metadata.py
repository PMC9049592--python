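"""Metadata extraction: abstract cases, title reconstruction, captions, front matter."""

import pytest

from paperblocks.blocks import build_document_model
from paperblocks.fixtures import FixtureSpec, generate_article
from paperblocks.metadata import (
    extract_abstract,
    extract_captions,
    extract_front_matter,
    extract_keywords,
    extract_metadata,
    extract_title,
)
from paperblocks.templates import GENERIC

from conftest import make_page, make_raw_block


def first_page(model):
    return model.page_blocks(0)


@pytest.mark.parametrize("case", [1, 2, 3])
def test_abstract_cases_recover_truth(case):
    model, truth = generate_article(FixtureSpec(seed=11, abstract_case=case))
    text, tag, _ = extract_abstract(first_page(model), GENERIC)
    assert tag == case
    assert text == truth.abstract


def test_abstract_case2_requires_alignment_below():
    prose = "word " * 60
    pages = [make_page([
        make_raw_block("Abstract", bbox=(57, 700, 110, 712)),
        # misaligned block below the identifier
        make_raw_block(prose, bbox=(300, 600, 560, 680)),
        # aligned block, further down
        make_raw_block(prose.strip(), bbox=(57, 450, 530, 590)),
    ])]
    model = build_document_model(pages)
    text, tag, claimed = extract_abstract(first_page(model), GENERIC)
    assert tag == 2
    assert text == prose.strip()
    assert len(claimed) == 2


def test_abstract_case3_filtration_skips_introduction_body():
    filler = lambda n: " ".join(f"w{i}" for i in range(n))
    pages = [make_page([
        make_raw_block("1. Introduction", bbox=(57, 700, 150, 712)),
        # largest block, but immediately preceded by an Introduction heading
        make_raw_block(filler(80), bbox=(57, 400, 555, 690)),
        # second-largest qualifying block: the actual abstract
        make_raw_block(filler(50), bbox=(57, 150, 530, 390)),
    ])]
    model = build_document_model(pages)
    text, tag, _ = extract_abstract(first_page(model), GENERIC)
    assert tag == 3
    assert text == filler(50)


def test_abstract_absent_when_nothing_qualifies():
    model = build_document_model([make_page([make_raw_block("short text only")])])
    text, tag, claimed = extract_abstract(first_page(model), GENERIC)
    assert text is None and claimed == set()


def test_title_character_reconstruction_strips_merged_banner():
    banner = "Research Article\n"
    big = "Big Title Here Now"
    text = banner + big
    sizes = [8.0] * len(banner) + [18.0] * len(big)
    pages = [make_page([
        make_raw_block(text, sizes=sizes, bbox=(106, 700, 506, 740)),
        make_raw_block("body " * 30, bbox=(57, 300, 555, 600)),
    ])]
    model = build_document_model(pages)
    title, _ = extract_title(first_page(model), GENERIC)
    assert title == "Big Title Here Now"


def test_title_absent_when_nothing_centered():
    pages = [make_page([
        make_raw_block("Off To The Left Title", size=18.0, bbox=(10, 700, 200, 740)),
    ])]
    model = build_document_model(pages)
    title, claimed = extract_title(first_page(model), GENERIC)
    assert title is None and claimed == set()


def test_title_invariant_to_appending_non_centered_blocks(default_article):
    model, truth = default_article
    title, _ = extract_title(first_page(model), GENERIC)
    extra = build_document_model(
        [make_page(
            [
                {"text": b.text, "font_sizes": list(b.chars.font_sizes),
                 "bbox": [b.bbox.x0, b.bbox.y0, b.bbox.x1, b.bbox.y1]}
                for b in model.page_blocks(0)
            ]
            + [make_raw_block("Loud Margin Note Text", size=30.0, bbox=(0, 10, 90, 40))]
        )]
    )
    title2, _ = extract_title(first_page(extra), GENERIC)
    assert title == title2 == truth.title


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Keywords: solar; perovskite; stability", ["solar", "perovskite", "stability"]),
        ("KEYWORDS text mining, PDF", ["text mining", "PDF"]),
        ("no label anywhere", []),
    ],
)
def test_keyword_splitting(text, expected):
    model = build_document_model([make_page([make_raw_block(text)])])
    keywords, _ = extract_keywords(first_page(model), GENERIC)
    assert keywords == expected


def test_caption_sorting_and_patterns():
    pages = [make_page([
        make_raw_block("Figure 2 Low-level workflow of the system"),
        make_raw_block("Figure 1 High-level workflow of the system"),
        make_raw_block("Fig. 3. Schematic of the detector"),
        make_raw_block("Figure1glued caption without a space"),
        make_raw_block("Table 1 Evaluation results"),
    ])]
    model = build_document_model(pages)
    captions, claimed = extract_captions(list(model.blocks), GENERIC)
    assert [(c.label_kind, c.sequence_number) for c in captions] == [
        ("figure", 1), ("figure", 2), ("figure", 3), ("table", 1)
    ]
    assert all(c.text.split()[0] in ("Figure", "Fig.", "Table") for c in captions)
    assert len(claimed) == 4  # the glued block is not matched


def test_front_matter_journal_line_decomposition():
    pages = [make_page([
        make_raw_block("J. Example Chem. 2020, 12, 345−360"),
        make_raw_block("doi.org/10.1021/acs.jcim.1c01198,"),
    ])]
    model = build_document_model(pages)
    front = extract_front_matter(first_page(model), GENERIC)
    assert front.journal_name == "J. Example Chem."
    assert (front.year, front.volume, front.page_range) == (2020, "12", "345−360")
    assert front.doi == "10.1021/acs.jcim.1c01198"


def test_author_line_splitting(default_article):
    model, truth = default_article
    record, _ = extract_metadata(model, GENERIC)
    assert record.authors == truth.authors
    assert record.emails == truth.emails


def test_extracted_strings_are_substrings_of_page_text(default_article):
    model, _ = default_article
    record, _ = extract_metadata(model, GENERIC)
    page_text = " ".join(" ".join(b.text.split()) for b in first_page(model))
    doc_text = " ".join(" ".join(b.text.split()) for b in model.blocks)
    for value in [record.title, record.abstract, record.doi] + record.keywords:
        if value:
            assert value in page_text or value in doc_text
    for caption in record.captions:
        assert caption.text in doc_text
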