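"""Reference flattening, marker spans, slicing, entry parsing."""

import pytest

from paperblocks.fixtures import FixtureSpec, generate_article
from paperblocks.references import (
    FlatReferenceString,
    build_slicing_indexes,
    find_marker_spans,
    flatten_reference_blocks,
    parse_reference_entry,
    slice_references,
    ReferenceEntry,
)
from paperblocks.sections import SPACE_OCCUPIER
from paperblocks.templates import GENERIC


def test_flatten_joins_fragments_and_skips_occupiers():
    slots = ["[1] A. One,", "J. Ex. 2020.", SPACE_OCCUPIER, "[2] B. Two et al."]
    flat = flatten_reference_blocks(slots)
    assert flat.text == "[1] A. One, J. Ex. 2020. [2] B. Two et al."
    assert len(flat.source_slots) == 3


def test_flatten_single_block_identity():
    flat = flatten_reference_blocks(["[1] Lone entry."])
    assert flat.text == "[1] Lone entry."


def test_marker_spans_consecutive_run():
    text = "preamble  [1] first [2] second [3] third [4] fourth [5] fifth"
    spans = find_marker_spans(FlatReferenceString(text), GENERIC)
    assert [s.sequence_number for s in spans] == [1, 2, 3, 4, 5]
    starts = [s.start for s in spans]
    assert starts == sorted(starts)


def test_in_text_citation_rejected_by_run_constraint():
    text = "as shown in [3] for details [1] First ref [2] Second ref"
    spans = find_marker_spans(FlatReferenceString(text), GENERIC)
    assert [s.sequence_number for s in spans] == [1, 2]


def test_no_markers_yields_empty():
    assert find_marker_spans(FlatReferenceString("no digits at all"), GENERIC) == []
    assert find_marker_spans(FlatReferenceString("[7] starts too late"), GENERIC) == []


def test_slicing_indexes_offset_rule():
    spans = [
        # marker starts as printed in a five-entry reference string
        type("S", (), {"start": s, "end": s + 4, "sequence_number": i + 1})()
        for i, s in enumerate([10, 104, 237, 353, 420])
    ]
    pairs = build_slicing_indexes(spans, 500)
    assert pairs == [(10, 104), (104, 237), (237, 353), (353, 420), (420, 500)]
    assert build_slicing_indexes([], 100) == []


def test_slices_partition_the_flat_string():
    entries_text = ["[1] Alpha one.", "[2] Beta two.", "[3] Gamma three."]
    flat = flatten_reference_blocks(entries_text)
    spans = find_marker_spans(flat, GENERIC)
    pairs = build_slicing_indexes(spans, len(flat.text))
    entries = slice_references(flat, pairs, spans)
    assert [e.sequence_number for e in entries] == [1, 2, 3]
    assert [e.raw for e in entries] == entries_text
    reconstructed = " ".join(e.raw for e in entries)
    assert reconstructed == flat.text[spans[0].start:]


def test_refragmenting_does_not_change_entries():
    """Different block splits of the same section flatten identically."""
    entries = ["[1] A. One, J. Ex. 2020, 1, 2−3.", "[2] B. Two, Ann. Rev. 2019, 4, 5−6."]
    joined = " ".join(entries)
    words = joined.split()
    split_a = [" ".join(words[:3]), " ".join(words[3:9]), " ".join(words[9:])]
    split_b = [" ".join(words[:5]), " ".join(words[5:])]
    for slots in ([joined], split_a, split_b):
        flat = flatten_reference_blocks(slots)
        spans = find_marker_spans(flat, GENERIC)
        pairs = build_slicing_indexes(spans, len(flat.text))
        out = [e.raw for e in slice_references(flat, pairs, spans)]
        assert out == entries


def test_parse_reference_entry_fields():
    entry = ReferenceEntry("[1] A. One, B. Two, J. Good Sci. 2019, 12, 345−360.", 1)
    parsed = parse_reference_entry(entry)
    assert parsed.year == 2019
    assert parsed.pages == "345−360"
    assert parsed.authors == "A. One, B. Two"
    assert parsed.journal == "J. Good Sci."
    assert parsed.raw == entry.raw


def test_parse_unstructured_entry_keeps_raw_only():
    parsed = parse_reference_entry(ReferenceEntry("[2] Anonymous note.", 2))
    assert parsed.raw == "[2] Anonymous note."
    assert parsed.year is None and parsed.pages is None


def test_fixture_references_round_trip():
    model, truth = generate_article(FixtureSpec(seed=5, n_refs=7, fragment_refs=True))
    from paperblocks.pipeline import run_pipeline
    record = run_pipeline(model)
    assert [r.raw for r in record.references] == truth.references
    assert [r.sequence_number for r in record.references] == list(range(1, 8))
    for r in record.references:
        assert r.year is not None and 1800 <= r.year <= 2100
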