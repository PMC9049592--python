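"""Similarity-thresholded evaluation: precision, recall and F-score per field.

An extracted string counts as a true positive when its Gestalt similarity to
the corresponding ground-truth string reaches the threshold (default 0.9 — a
band wide enough to forgive formatting and encoding variation while rejecting
genuinely wrong text).  Singleton fields (title, abstract, DOI) compare one
string against one; multi-item fields (keywords, authors, sections, captions,
references) are paired greedily by descending similarity before counting.

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = 2 * precision * recall / (precision + recall)

Any metric whose denominator is zero is reported as absent rather than 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .similarity import canonicalize, gestalt_similarity

__all__ = [
    "EvaluationCounts",
    "EvaluationReport",
    "DEFAULT_THRESHOLD",
    "REPORT_FIELDS",
    "score_field",
    "aggregate_report",
    "read_ground_truth_json",
    "read_ground_truth_xml",
    "truth_fields_from_mapping",
    "record_fields",
]

DEFAULT_THRESHOLD = 0.9

#: Report columns: metadata, body, references.
REPORT_FIELDS = (
    "title",
    "abstract",
    "doi",
    "journal",
    "keywords",
    "author",
    "sections",
    "captions",
    "refs",
)

_MULTI_FIELDS = {"journal", "keywords", "author", "sections", "captions", "refs"}


@dataclass
class EvaluationCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "EvaluationCounts") -> "EvaluationCounts":
        return EvaluationCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    @property
    def precision(self) -> float | None:
        total = self.tp + self.fp
        return self.tp / total if total else None

    @property
    def recall(self) -> float | None:
        total = self.tp + self.fn
        return self.tp / total if total else None

    @property
    def f_score(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)


def _similar(a: str, b: str, threshold: float) -> tuple[bool, float]:
    score = gestalt_similarity(canonicalize(a), canonicalize(b))
    return score.dro >= threshold, score.dro


def score_field(
    extracted: str | list[str] | None,
    truth: str | list[str] | None,
    threshold: float = DEFAULT_THRESHOLD,
) -> EvaluationCounts:
    """Count TP/FP/FN for one field.

    Singleton semantics: a present extraction is TP if it clears the
    threshold, FP otherwise; an absent extraction against present truth is an
    FN.  Multi-item semantics: candidate pairs above threshold are accepted
    greedily by descending similarity; leftovers on the extracted side are
    FPs, on the truth side FNs.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    ext_list = _as_list(extracted)
    truth_list = _as_list(truth)
    if isinstance(extracted, list) or isinstance(truth, list):
        return _score_multi(ext_list, truth_list, threshold)
    if not ext_list and not truth_list:
        return EvaluationCounts()
    if not ext_list:
        return EvaluationCounts(fn=1)
    if not truth_list:
        return EvaluationCounts(fp=1)
    ok, _ = _similar(ext_list[0], truth_list[0], threshold)
    return EvaluationCounts(tp=1) if ok else EvaluationCounts(fp=1)


def _as_list(value: str | list[str] | None) -> list[str]:
    if value is None:
        return []
    if isinstance(value, str):
        return [value] if value.strip() else []
    return [v for v in value if str(v).strip()]


def _score_multi(
    extracted: list[str], truth: list[str], threshold: float
) -> EvaluationCounts:
    scored = []
    for i, e in enumerate(extracted):
        for j, t in enumerate(truth):
            ok, dro = _similar(str(e), str(t), threshold)
            if ok:
                scored.append((dro, i, j))
    scored.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_e: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, i, j in scored:
        if i in used_e or j in used_t:
            continue
        used_e.add(i)
        used_t.add(j)
        tp += 1
    return EvaluationCounts(
        tp=tp, fp=len(extracted) - tp, fn=len(truth) - tp
    )


@dataclass
class EvaluationReport:
    """Per-field counts at a fixed similarity threshold."""

    fields: dict[str, EvaluationCounts] = field(default_factory=dict)
    similarity_threshold: float = DEFAULT_THRESHOLD

    def precision_table(self) -> dict[str, float | None]:
        """Per-field precision on the percent display scale."""
        return {
            name: (None if c.precision is None else round(100 * c.precision, 1))
            for name, c in self.fields.items()
        }

    def to_json(self) -> str:
        payload = {
            "similarity_threshold": self.similarity_threshold,
            "fields": {
                name: {
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "precision": c.precision,
                    "recall": c.recall,
                    "f_score": c.f_score,
                }
                for name, c in self.fields.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def to_text(self) -> str:
        """Human-readable precision table (percent scale)."""
        names = list(self.fields)
        header = "field      " + "".join(f"{n:>10}" for n in names)
        row = "precision  " + "".join(
            f"{(100 * c.precision):>10.1f}" if c.precision is not None else f"{'-':>10}"
            for c in self.fields.values()
        )
        return header + "\n" + row


def aggregate_report(
    per_field: dict[str, EvaluationCounts],
    threshold: float = DEFAULT_THRESHOLD,
) -> EvaluationReport:
    """Assemble per-field counts into a report with the standard column set."""
    fields = {name: per_field.get(name, EvaluationCounts()) for name in REPORT_FIELDS}
    for name, counts in per_field.items():
        if name not in fields:
            fields[name] = counts
    return EvaluationReport(fields=fields, similarity_threshold=threshold)


# ---------------------------------------------------------------------------
# Ground-truth ingestion and record/truth field mapping
# ---------------------------------------------------------------------------

def read_ground_truth_json(path: str | Path) -> dict:
    """Fixture ground-truth schema: title/abstract/doi/journal/keywords/
    authors/sections/captions/references."""
    return json.loads(Path(path).read_text())


def read_ground_truth_xml(path: str | Path) -> dict:
    """Best-effort mapping of publisher XML/HTML markup to truth fields.

    Recognized tags (searched anywhere, namespaces ignored): title/
    article-title, abstract, doi (or elements whose text starts with "10." and
    an attribute naming a DOI), keyword/kwd, author/creator, section titles
    (sec/title or h2), caption, ref/reference.
    """
    from lxml import etree

    tree = etree.parse(str(path), etree.XMLParser(recover=True))

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1].lower() if isinstance(tag, str) else ""

    def text_of(el) -> str:
        return " ".join(" ".join(el.itertext()).split())

    truth: dict = {}
    keywords: list[str] = []
    authors: list[str] = []
    sections: list[dict] = []
    captions: list[str] = []
    references: list[str] = []
    for el in tree.iter():
        tag = local(el.tag)
        if tag in ("title", "article-title") and "title" not in truth:
            truth["title"] = text_of(el)
        elif tag == "abstract" and "abstract" not in truth:
            truth["abstract"] = text_of(el)
        elif tag == "doi" and "doi" not in truth:
            truth["doi"] = text_of(el)
        elif tag in ("keyword", "kwd"):
            keywords.append(text_of(el))
        elif tag in ("author", "creator"):
            authors.append(text_of(el))
        elif tag == "sec":
            heading = next(
                (c for c in el if local(c.tag) in ("title", "h2")), None
            )
            if heading is not None:
                sections.append({"title": text_of(heading), "text": ""})
        elif tag == "caption":
            captions.append(text_of(el))
        elif tag in ("ref", "reference"):
            references.append(text_of(el))
    if keywords:
        truth["keywords"] = keywords
    if authors:
        truth["authors"] = authors
    if sections:
        truth["sections"] = sections
    if captions:
        truth["captions"] = captions
    if references:
        truth["references"] = references
    return truth


def _journal_items(journal: dict | None) -> list[str]:
    if not journal:
        return []
    items = []
    for key in ("name", "year", "volume", "pages"):
        value = journal.get(key)
        if value not in (None, ""):
            items.append(str(value))
    return items


def truth_fields_from_mapping(truth: dict) -> dict[str, str | list[str] | None]:
    """Ground-truth mapping -> the report's per-field comparison values.

    Section text is deliberately ignored: section extraction is judged on
    titles, body text being too sensitive to figure/table/encoding noise.
    """
    sections = truth.get("sections") or []
    return {
        "title": truth.get("title"),
        "abstract": truth.get("abstract"),
        "doi": truth.get("doi"),
        "journal": _journal_items(truth.get("journal")),
        "keywords": truth.get("keywords") or [],
        "author": truth.get("authors") or [],
        "sections": [s["title"] for s in sections],
        "captions": truth.get("captions") or [],
        "refs": truth.get("references") or [],
    }


def record_fields(record: dict) -> dict[str, str | list[str] | None]:
    """ArticleRecord JSON mapping -> the report's per-field comparison values."""
    journal = record.get("journal") or {}
    return {
        "title": record.get("title"),
        "abstract": record.get("abstract"),
        "doi": record.get("doi"),
        "journal": _journal_items(journal),
        "keywords": record.get("keywords") or [],
        "author": record.get("authors") or [],
        "sections": [s["title"] for s in record.get("sections") or []],
        "captions": [c["text"] for c in record.get("captions") or []],
        "refs": [r["raw"] for r in record.get("references") or []],
    }
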