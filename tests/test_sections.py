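"""Noise patterns, heading candidates, cleaning, location pairs, segmentation."""

import pytest

from paperblocks.blocks import build_document_model
from paperblocks.fixtures import FixtureSpec, generate_article
from paperblocks.sections import (
    FRONT_MATTER_TITLE,
    SPACE_OCCUPIER,
    WHOLE_DOCUMENT_TITLE,
    HeadingCandidates,
    LocationPair,
    build_body_list,
    build_location_pairs,
    build_noise_patterns,
    clean_candidates,
    collect_heading_candidates,
    is_reference_title,
    segment_body,
)
from paperblocks.templates import GENERIC

from conftest import make_page, make_raw_block


def three_page_model(page_numbers=("1", "2", "3")):
    pages = []
    for i, num in enumerate(page_numbers):
        pages.append(make_page([
            make_raw_block(f"J. Name 202{i}"),   # running header, digits vary
            make_raw_block(num),
            make_raw_block([
                "opening page prose about lattice strain and carrier transport",
                "second page discusses entirely different deposition kinetics instead",
                "closing page concludes with recombination lifetime measurements",
            ][i]),
        ]))
    return build_document_model(pages)


def test_running_header_detected_across_pages():
    model = three_page_model()
    noise = build_noise_patterns(model, GENERIC)
    assert any(p.fullmatch("J. Name 2020") for p in noise.header_patterns)
    assert any(p.fullmatch("J. Name 2024") for p in noise.header_patterns)  # digits unify


def test_page_numbers_matched_as_noise():
    model = three_page_model()
    noise = build_noise_patterns(model, GENERIC)
    for num in ("1", "2", "3", "17"):
        assert noise.matches(num)


def test_disjoint_pages_produce_no_header_patterns():
    pages = [
        make_page([make_raw_block("alpha beta gamma delta words here")]),
        make_page([make_raw_block("completely unrelated second page text")]),
    ]
    noise = build_noise_patterns(build_document_model(pages), GENERIC)
    assert noise.header_patterns == []
    assert noise.page_number_pattern is not None
    assert noise.caption_pattern is not None


def test_single_page_document_only_structural_patterns():
    model = build_document_model([make_page([make_raw_block("lone page text")])])
    noise = build_noise_patterns(model, GENERIC)
    assert noise.header_patterns == []


def heading_model():
    filler = "plain body paragraph with quite a few words " * 2
    pages = [make_page([
        make_raw_block(filler, size=10.0),
        make_raw_block("1. Introduction", size=10.0),
        make_raw_block(filler, size=10.0),
        make_raw_block("2. Methods", size=10.0),
        make_raw_block("3.1 Subsection heading", size=10.0),
        make_raw_block("word " * 80, size=10.0),
    ])]
    return build_document_model(pages)


def test_numbered_heading_candidates_collected():
    candidates = collect_heading_candidates(heading_model(), GENERIC)
    assert candidates.string == ["1. Introduction", "2. Methods", "3.1 Subsection heading"]
    assert candidates.location == [1, 3, 4]


def test_unnumbered_heading_needs_larger_font():
    filler = "body words repeated enough times to set the modal font " * 3
    pages = [make_page([
        make_raw_block(filler, size=10.0),
        make_raw_block("Results and Discussion", size=12.0),
        make_raw_block("short but body-sized", size=10.0),
        make_raw_block(filler, size=10.0),
    ])]
    candidates = collect_heading_candidates(build_document_model(pages), GENERIC)
    assert candidates.string == ["Results and Discussion"]


def test_cleaning_retains_largest_font_indexes():
    candidates = HeadingCandidates(
        location=[10, 25, 50, 68, 90, 120],
        string=[
            "1. Introduction", "2. Experimental", "6. Intended Error",
            "3. Results", "4. Discussion", "5. Conclusions",
        ],
        font=[10.003, 10.003, 9.0, 10.003, 10.003, 10.003],
    )
    cleaned = clean_candidates(candidates)
    assert max(candidates.font) == 10.003
    assert cleaned.location == [10, 25, 68, 90, 120]
    assert "6. Intended Error" not in cleaned.string


def test_cleaning_identity_and_tie_handling():
    same = HeadingCandidates([1, 2], ["A word", "B word"], [10.0, 10.0])
    cleaned = clean_candidates(same)
    assert cleaned.string == same.string
    mixed = HeadingCandidates([1, 2, 3, 4], ["a", "b", "c", "d"], [10.0, 10.0, 8.0, 10.0])
    assert clean_candidates(mixed).location == [1, 2, 4]


def test_cleaned_lists_are_parallel_index_subsequences():
    mixed = HeadingCandidates(
        [3, 9, 14, 20], ["w", "x", "y", "z"], [9.0, 11.0, 11.0, 10.96]
    )
    cleaned = clean_candidates(mixed)
    assert len(cleaned.location) == len(cleaned.string) == len(cleaned.font)
    kept = set(zip(cleaned.location, cleaned.string))
    assert kept <= set(zip(mixed.location, mixed.string))
    assert cleaned.location == [9, 14, 20]  # 10.96 within 0.05 pt of 11.0


def test_location_pairs_chain_with_front_matter():
    cleaned = HeadingCandidates([10, 25], ["Introduction", "Methods"], [10.0, 10.0])
    pairs = build_location_pairs(cleaned, 40)
    assert pairs[0] == LocationPair(0, 10, FRONT_MATTER_TITLE)
    assert pairs[1] == LocationPair(10, 25, "Introduction")
    assert pairs[2] == LocationPair(25, 40, "Methods")
    for a, b in zip(pairs, pairs[1:]):
        assert a.end == b.start


def test_location_pairs_edge_cases():
    single = HeadingCandidates([0], ["Only"], [10.0])
    pairs = build_location_pairs(single, 5)
    assert pairs == [LocationPair(0, 5, "Only")]

    chained = build_location_pairs(
        HeadingCandidates([3, 7, 9], ["a", "b", "c"], [1.0, 1.0, 1.0]), 12
    )
    assert [(p.start, p.end) for p in chained[1:]] == [(3, 7), (7, 9), (9, 12)]

    empty = build_location_pairs(HeadingCandidates(), 6)
    assert empty == [LocationPair(0, 6, WHOLE_DOCUMENT_TITLE)]


def test_body_list_conserves_slot_count(default_article):
    model, _ = default_article
    noise = build_noise_patterns(model, GENERIC)
    body = build_body_list(model, noise)
    assert len(body) == len(model)
    occupiers = body.count(SPACE_OCCUPIER)
    # 2 noise blocks per page (header + page number) and the captions
    assert occupiers >= 2 * model.n_pages


def test_segmentation_skips_occupiers():
    body = ["front", "Heading One", "a", SPACE_OCCUPIER, "b", "Heading Two", "c"]
    pairs = [
        LocationPair(0, 1, FRONT_MATTER_TITLE),
        LocationPair(1, 5, "Heading One"),
        LocationPair(5, 7, "Heading Two"),
    ]
    sectioned = segment_body(body, pairs)
    assert sectioned.front_matter == "front"
    assert sectioned.as_mapping() == {"Heading One": "a b", "Heading Two": "c"}
    assert SPACE_OCCUPIER not in " ".join(s.text for s in sectioned.sections)


def test_segmentation_partition_property(default_article):
    """Every slot lands in exactly one of front matter / one section."""
    model, _ = default_article
    template = GENERIC
    from paperblocks.metadata import extract_metadata
    _, claimed = extract_metadata(model, template)
    candidates = collect_heading_candidates(model, template, exclude=claimed)
    cleaned = clean_candidates(candidates)
    pairs = build_location_pairs(cleaned, len(model))
    covered = []
    for p in pairs:
        covered.extend(range(p.start, p.end))
    assert sorted(covered) == list(range(len(model)))


def test_out_of_bounds_pair_raises():
    with pytest.raises(ValueError, match="inconsistent"):
        segment_body(["a", "b"], [LocationPair(0, 5, "X")])


def test_extra_duplicate_header_page_does_not_change_sections():
    spec = FixtureSpec(seed=21, n_pages=4)
    model, truth = generate_article(spec)
    bigger, truth2 = generate_article(
        FixtureSpec(seed=21, n_pages=5)
    )
    from paperblocks.pipeline import run_pipeline
    sections = [(s.title, s.text) for s in run_pipeline(model).body.sections]
    assert sections == [(s["title"], s["text"]) for s in truth.sections]
    sections2 = [(s.title, s.text) for s in run_pipeline(bigger).body.sections]
    assert sections2 == [(s["title"], s["text"]) for s in truth2.sections]


def test_reference_title_detection():
    assert is_reference_title("References")
    assert is_reference_title("5. Bibliography")
    assert is_reference_title("LITERATURE  CITED")
    assert not is_reference_title("Results")
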