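# Methods

## The extraction model

`paperblocks` treats an article as an ordered stream of positioned text blocks
— the unit a PDF layout-analysis backend naturally produces — and reconstructs
logical structure purely from block-level evidence: position, extent, font
sizes, word counts, repetition across pages, and printed markers.  No
language model, no training corpus; every decision is a rule parameterized by
a publisher template.  The design optimizes precision over recall: a
database-building pipeline downstream is better served by a missing field than
by a wrong one.

Assumptions inherited from that design:

* the backend delivers blocks in correct reading order with per-character
  font sizes (multi-column reading-order inference is the backend's job);
* metadata lives on the first page; headings carry either a numeric prefix or
  a distinct (larger-than-body) font; references carry printed sequence
  numbers.  Author–year reference styles and image-based (OCR-requiring)
  documents are out of scope by construction.

## Tunable parameters

All thresholds live on the `Template` dataclass and are overridable per
publisher style via TOML/JSON configs.  The defaults are package choices for
single-column article layouts, in PDF points and tokens:

| parameter | default | meaning |
| --- | --- | --- |
| `title_center_tolerance` | 40 pt | max distance of a title block's x-center from the page x-center |
| `title_word_range` | (3, 40) tokens | word-count band for title candidates |
| `abstract_min_words` | 40 tokens | minimum length for an embedded-label or largest-area abstract |
| `abstract_align_tolerance` | 20 pt | left-edge tolerance for the separated-label abstract case |
| `noise_block_count` | 6 | leading blocks screened per page for repeated headers |
| `reference_marker_style` | bracketed | `[n]` vs `n.` vs `(n)` marker grammar |
| similarity threshold | 0.9 | Gestalt score for a true positive in evaluation (CLI `--threshold`) |

Fixed numerical choices, stated where they bite:

* **Title character filter** — within the winning title block only characters
  within 0.1 pt of the block's maximal character size are kept; this strips
  article-type banners or author lines merged into the title block by the
  backend.
* **Heading cleaning** — candidates within 0.05 pt of the maximal candidate
  font are retained; all ties at the maximum survive.  The tolerance absorbs
  backend rounding of font sizes (e.g. 10.003 pt vs 10.0 pt nominal).
* **Unnumbered-heading rule** — at most 6 words, no terminal period, dominant
  font more than 0.25 pt above the document's character-weighted modal font
  (the body-text estimate; ties in the mode resolve to the smaller size).
* **Separated-abstract alignment** — the body block must sit below the label
  and either overlap its x-interval by ≥ 0.9 of the narrower width or agree
  on the left edge within `abstract_align_tolerance`; publishers do not align
  the two blocks exactly.
* **Noise matching** — a leading block on a later page joins the header list
  when its digit-stripped text reaches Gestalt similarity 0.9 against the
  compare-list, so "Page 3" and "Page 4" variants unify; digit runs in the
  resulting search pattern generalize to `\d+`.  A candidate pattern is
  *confirmed* only if it matches leading blocks on at least two distinct
  pages: repetition across pages is the defining property of page furniture,
  and the confirmation step keeps one-off body text (a reference fragment
  shaped like the journal line, say) from being deleted as a header.

## Span and sentinel conventions

Location pairs are half-open `[start, end)` over universal sequence numbers;
the heading block sits at `start`, titles the section, and is excluded from
its text, so consecutive pairs chain without overlap and the slots partition
the document exactly.  A leading pair captures front matter (everything
before the first heading) and the last pair is closed at the total block
count; with no headings at all a single whole-document pair with a sentinel
title is emitted.  Noise blocks are replaced in the body list by a reserved
zero-width space-occupier token — never emitted into output — so the list
keeps one slot per sequence number and pair indexing stays valid.

Reference marker spans are the regex match spans of the marker pattern
including one optional trailing space; entry *i* runs from the start of
marker *i* to the start of marker *i + 1* (the last entry to the string end).
Only the maximal consecutive run of markers starting at 1 is accepted, which
rejects in-text bracket citations.  Field parsing of entries (authors,
journal, year, pages) is best-effort and explicitly lossy; the raw substring
is the contract.

## Similarity and evaluation

The Gestalt (Ratcliff–Obershelp) matching-character count anchors on the
longest common substring and recurses on both flanks; anchor ties break
leftmost-in-S1 then leftmost-in-S2, the same convention as stdlib
`difflib.SequenceMatcher(autojunk=False)`, which serves as an independent
cross-check in the tests alongside a brute-force enumeration oracle.  Two
empty strings score 1.  Strings are NFC-normalized and whitespace-collapsed
before comparison; case is preserved.

Singleton fields score one TP/FP per article (absent extraction against
present truth is an FN); multi-item fields pair extracted and truth items
greedily by descending similarity above the threshold.  Section extraction is
judged on titles, not body text — body comparisons are dominated by
figure/table/encoding noise rather than by segmentation quality.  Metrics
with zero denominators are reported as absent, never as zero.

## The fixture generator

The generator emulates the block-level phenomena each stage depends on:
centered large-font title (18 pt) over heading (12 pt) over body (10 pt)
text; an author line, affiliation-with-email line, journal line and DOI line;
the three abstract layouts; numbered or unnumbered headings; per-page running
headers and page numbers (toggleable); captions as separate blocks; and
numbered references fragmented across 2–3 blocks each (toggleable).  Default
articles are 4 pages (front page, two body pages, reference page) with 3
sections and 5 references, roughly 40 blocks; corpus generation walks the
3 abstract-cases × 2 heading-styles grid cyclically with per-article derived
seeds, so 6 articles already cover every combination.  Prose is seeded
pseudo-text from a fixed vocabulary.

What the fixtures do **not** emulate — and hence what passing closure tests
does not demonstrate: two-column flow and reading-order errors, merged
title/author blocks (exercised separately in unit tests), tables and display
formulae, subcaptions, encoding damage, publisher layouts that depart from
the single-column archetype, and scanned pages.  On real corpora the same
rules yield substantially lower precision; the fixture suite verifies the
logic, not field performance.

Test and acceptance problem sizes are chosen to exercise every code path at
desk scale: the closure suite runs a 50-article corpus (all grid cells,
noise invariance checked per article), and the similarity oracle check
exhausts all string pairs of combined length ≤ 12 over a 3-letter alphabet
through canonical representatives under alphabet renaming (both routes
compare characters only by equality, so the matching count depends only on
the equality pattern; the test also verifies that the representatives expand
to exactly the 9,964,519 ordered pairs of the domain).

## Known limitations

* Template auto-selection relies on printable evidence; articles published by
  one house under another's layout select the wrong template.
* The journal-line parser expects a "name year, volume, pages" shape; swapped
  year/volume orders mis-parse.
* Caption text keeps its "Figure N" prefix and subcaptions are not split.
* Unnumbered reference styles yield zero entries by design.
* The author-line heuristic (positional sandwich between title and abstract,
  sub-title font, no affiliation markers) fails when author and title blocks
  merge — partially mitigated by the title character filter, not eliminated.
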