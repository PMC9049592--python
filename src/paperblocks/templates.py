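"""Publisher-style extraction templates and automatic template selection.

A template bundles every tunable rule and threshold the extraction stages
consume: title centering tolerance, abstract length/alignment thresholds,
heading rules, reference marker style, noise screening depth, and the label
patterns for DOIs, keywords and captions.  A small built-in registry covers a
generic style plus publisher-flavoured variants; users can load more from
TOML/JSON config files.

Template auto-selection scores printable evidence on the document: a DOI
prefix match is the most publisher-discriminative signal and counts double; a
publisher name string on page 1 and a layout fingerprint count once each.
Ties resolve by registry order and a generic fallback is always available, so
selection is total and deterministic.
"""

from __future__ import annotations

import json
import re
import tomllib
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Sequence

from .blocks import DocumentModel

__all__ = [
    "Template",
    "TemplateError",
    "GENERIC",
    "builtin_registry",
    "select_template",
    "load_template",
    "load_registry",
]


class TemplateError(ValueError):
    """A template config is malformed (unknown field or non-compiling pattern)."""


_DEFAULT_HEADING_RULES = ("numbered", "unnumbered")

# Default numeric thresholds are artifact defaults chosen for single-column
# article layouts; every one of them is template-overridable.
@dataclass(frozen=True)
class Template:
    name: str = "generic"
    title_center_tolerance: float = 40.0          # pt
    title_word_range: tuple[int, int] = (3, 40)   # tokens
    abstract_min_words: int = 40                  # tokens
    abstract_align_tolerance: float = 20.0        # pt
    heading_rules: tuple[str, ...] = _DEFAULT_HEADING_RULES
    heading_uses_font: bool = True
    reference_marker_style: str = "bracketed"     # bracketed | dotted | parenthesized
    noise_block_count: int = 6                    # blocks screened per page
    doi_pattern: str = r"10\.\d{4,9}/\S+"
    keyword_label: str = r"keywords?"
    caption_labels: str = r"(Figure|Fig\.?|Table|Scheme)\s+(\d+)"
    # selector evidence
    selector_doi_prefixes: tuple[str, ...] = ()
    selector_publisher_names: tuple[str, ...] = ()
    selector_fingerprint: str = ""    # layout-fingerprint regex on page-1 text

    def __post_init__(self) -> None:
        if self.title_word_range[0] < 1:
            raise TemplateError("title_word_range minimum must be >= 1")
        if self.noise_block_count < 1:
            raise TemplateError("noise_block_count must be >= 1")
        if self.reference_marker_style not in ("bracketed", "dotted", "parenthesized"):
            raise TemplateError(
                f"unknown reference_marker_style '{self.reference_marker_style}'"
            )
        for attr in ("doi_pattern", "keyword_label", "caption_labels",
                     "selector_fingerprint"):
            pattern = getattr(self, attr)
            try:
                re.compile(pattern)
            except re.error as exc:
                raise TemplateError(
                    f"pattern for '{attr}' does not compile: {pattern!r} ({exc})"
                ) from exc
        for rule in self.heading_rules:
            if rule not in ("numbered", "unnumbered"):
                raise TemplateError(f"unknown heading rule '{rule}'")


GENERIC = Template()

_ELSEVIER = Template(
    name="elsevier",
    title_center_tolerance=80.0,  # Elsevier titles are slightly offset
    selector_doi_prefixes=("10.1016/",),
    selector_publisher_names=("elsevier", "sciencedirect"),
)

_ACS = Template(
    name="acs",
    selector_doi_prefixes=("10.1021/",),
    selector_publisher_names=("american chemical society", "acs publications"),
)

_RSC = Template(
    name="rsc",
    heading_rules=("unnumbered", "numbered"),
    selector_doi_prefixes=("10.1039/",),
    selector_publisher_names=("royal society of chemistry",),
)


def builtin_registry() -> list[Template]:
    """Built-in templates; the generic fallback is always last."""
    return [_ELSEVIER, _ACS, _RSC, GENERIC]


def _selector_score(template: Template, first_page_text: str) -> int:
    text = first_page_text.lower()
    score = 0
    if any(prefix in text for prefix in template.selector_doi_prefixes):
        score += 2
    if any(name.lower() in text for name in template.selector_publisher_names):
        score += 1
    if template.selector_fingerprint and re.search(
        template.selector_fingerprint, first_page_text, re.IGNORECASE | re.MULTILINE
    ):
        score += 1
    return score


def select_template(
    model: DocumentModel, registry: Sequence[Template] | None = None
) -> Template:
    """Pick the template whose selector evidence scores highest on page 1.

    Pure function of (model, registry); ties break by registry order and the
    generic template (score floor 0) guarantees a result.
    """
    if registry is None:
        registry = builtin_registry()
    if not registry:
        raise ValueError("template registry is empty")
    first_page_text = "\n".join(b.text for b in model.page_blocks(0))
    best = None
    best_score = 0
    for template in registry:
        score = _selector_score(template, first_page_text)
        if score > best_score:
            best, best_score = template, score
    if best is not None:
        return best
    # no positive evidence: fall back to the selector-free template
    return next(
        (
            t
            for t in registry
            if not t.selector_doi_prefixes
            and not t.selector_publisher_names
            and not t.selector_fingerprint
        ),
        registry[-1],
    )


_TUPLE_FIELDS = {
    "title_word_range",
    "heading_rules",
    "selector_doi_prefixes",
    "selector_publisher_names",
}


def load_template(path: str | Path) -> Template:
    """Load a template config (TOML or JSON); omitted fields keep defaults.

    Unknown fields and non-compiling patterns raise :class:`TemplateError`
    naming the offender.
    """
    path = Path(path)
    raw = path.read_bytes()
    if path.suffix.lower() == ".json":
        config = json.loads(raw)
    else:
        config = tomllib.loads(raw.decode())
    if not isinstance(config, dict):
        raise TemplateError("template config must be a table/object")
    known = {f.name for f in fields(Template)}
    updates = {}
    for key, value in config.items():
        if key not in known:
            raise TemplateError(f"unknown template field '{key}'")
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        updates[key] = value
    if "name" not in updates:
        updates["name"] = path.stem
    return replace(GENERIC, **updates)


def load_registry(directory: str | Path) -> list[Template]:
    """Scan a directory for ``*.toml``/``*.json`` template configs.

    Loaded templates precede the built-in registry; the generic fallback stays
    last.
    """
    directory = Path(directory)
    loaded = [
        load_template(p)
        for p in sorted(directory.iterdir())
        if p.suffix.lower() in (".toml", ".json")
    ]
    return loaded + builtin_registry()
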