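"""Five-stage extraction pipeline and the structured article record.

Stages run in order: preprocessing (block model), template selection,
metadata extraction, documentation-section detection, reference detection.
First-page blocks claimed by metadata extraction are withheld from section
detection; the section whose title names the bibliography is routed to the
reference stage instead of being emitted as body text.

The output :class:`ArticleRecord` serializes to a stable JSON schema (keys in
fixed order, absent fields present as null) and to a plain-text dump suitable
as input for a downstream text-mining tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .blocks import DocumentModel, NoTextLayerError, read_block_stream
from .metadata import MetadataRecord, extract_metadata
from .references import ReferenceEntry, extract_references
from .sections import (
    SectionedBody,
    build_body_list,
    build_location_pairs,
    build_noise_patterns,
    clean_candidates,
    collect_heading_candidates,
    is_reference_title,
    segment_body,
)
from .templates import Template, builtin_registry, select_template

__all__ = ["ArticleRecord", "run_pipeline", "emit"]


@dataclass
class ArticleRecord:
    metadata: MetadataRecord
    body: SectionedBody
    references: list[ReferenceEntry] = field(default_factory=list)
    template_used: str = "generic"
    warnings: list[str] = field(default_factory=list)

    def to_mapping(self) -> dict:
        """The documented output JSON schema; absent fields are null."""
        m = self.metadata
        return {
            "title": m.title,
            "authors": list(m.authors),
            "emails": list(m.emails),
            "abstract": m.abstract,
            "keywords": list(m.keywords),
            "doi": m.doi,
            "journal": {
                "name": m.journal_name,
                "year": m.year,
                "volume": m.volume,
                "issue": m.issue,
                "pages": m.page_range,
            },
            "sections": [
                {"title": s.title, "text": s.text} for s in self.body.sections
            ],
            "captions": [
                {
                    "kind": c.label_kind,
                    "number": c.sequence_number,
                    "text": c.text,
                }
                for c in m.captions
            ],
            "references": [
                {
                    "n": r.sequence_number,
                    "raw": r.raw,
                    "authors": r.authors,
                    "journal": r.journal,
                    "year": r.year,
                    "pages": r.pages,
                }
                for r in self.references
            ],
            "warnings": list(self.warnings),
            "template": self.template_used,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_mapping(), ensure_ascii=False, indent=1)

    def to_text(self) -> str:
        """Ordered plain-text dump: title, abstract, sections, references."""
        m = self.metadata
        lines: list[str] = []
        if m.title:
            lines += [m.title, ""]
        if m.abstract:
            lines += ["Abstract", m.abstract, ""]
        if m.keywords:
            lines += ["Keywords: " + "; ".join(m.keywords), ""]
        for section in self.body.sections:
            lines += [section.title, section.text, ""]
        if self.references:
            lines.append("References")
            lines += [r.raw for r in self.references]
        return "\n".join(lines).rstrip() + "\n"


def run_pipeline(
    source: DocumentModel | str | Path,
    template: Template | None = None,
    registry: list[Template] | None = None,
) -> ArticleRecord:
    """Run preprocess -> template select -> metadata -> sections -> references.

    ``source`` is a :class:`DocumentModel`, a block-stream JSON path, or a PDF
    path (requires the ``pdf`` extra).  A stage that finds nothing degrades to
    an absent field plus a warning; only an unreadable input raises.
    """
    model = _load(source)
    warnings: list[str] = []
    if template is None:
        template = select_template(model, registry)
    record_metadata, claimed = extract_metadata(model, template)

    noise = build_noise_patterns(model, template)
    candidates = collect_heading_candidates(model, template, exclude=claimed)
    cleaned = clean_candidates(candidates)
    pairs = build_location_pairs(cleaned, len(model))
    body_list = build_body_list(model, noise)
    sectioned = segment_body(body_list, pairs)

    references: list[ReferenceEntry] = []
    kept_sections = []
    for section in sectioned.sections:
        if is_reference_title(section.title):
            references = extract_references(section, template)
            if not references:
                warnings.append("reference section found but no numbered entries")
        else:
            kept_sections.append(section)
    sectioned = SectionedBody(sectioned.front_matter, kept_sections)

    for name in ("title", "abstract", "doi"):
        if getattr(record_metadata, name) is None:
            warnings.append(f"{name} not found")
    if not sectioned.sections:
        warnings.append("no body sections detected")

    return ArticleRecord(
        metadata=record_metadata,
        body=sectioned,
        references=references,
        template_used=template.name,
        warnings=warnings,
    )


def _load(source: DocumentModel | str | Path) -> DocumentModel:
    if isinstance(source, DocumentModel):
        return source
    path = Path(source)
    if path.suffix.lower() == ".pdf":
        from .pdfio import parse_pdf

        return parse_pdf(path)
    return read_block_stream(path)


def emit(record: ArticleRecord, format: str, path: str | Path | None = None) -> str:
    """Serialize a record to ``json`` or ``text``; optionally write it out."""
    if format == "json":
        payload = record.to_json()
    elif format == "text":
        payload = record.to_text()
    else:
        raise ValueError(f"unknown output format '{format}'")
    if path is not None:
        Path(path).write_text(payload)
    return payload
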