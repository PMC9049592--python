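"""Thin adapter over a PDF layout-analysis backend (pdfminer.six).

This is the only module that touches PDF bytes.  The backend does the layout
analysis — multi-column reading order included — and this adapter only
converts its text boxes into the backend-agnostic page stream consumed by
:func:`paperblocks.blocks.build_document_model`.

The backend is an optional dependency (the ``pdf`` extra); everything else in
the package runs on block-stream JSON without it.
"""

from __future__ import annotations

from pathlib import Path

from .blocks import DocumentModel, build_document_model

__all__ = ["MissingDependencyError", "parse_pdf"]


class MissingDependencyError(ImportError):
    """An optional PDF dependency is not installed."""


def parse_pdf(path: str | Path) -> DocumentModel:
    """Parse a born-digital PDF into a :class:`DocumentModel`.

    Raises
    ------
    MissingDependencyError
        If pdfminer.six is not installed.
    NoTextLayerError
        If the PDF has no extractable text (image-based scan).
    """
    try:
        from pdfminer.high_level import extract_pages
        from pdfminer.layout import LAParams, LTChar, LTTextContainer
    except ImportError as exc:
        raise MissingDependencyError(
            "parse_pdf requires pdfminer.six (install the 'pdf' extra)"
        ) from exc

    pages = []
    for layout in extract_pages(str(path), laparams=LAParams()):
        x0, y0, x1, y1 = layout.bbox
        page = {"width": x1 - x0, "height": y1 - y0, "blocks": []}
        for element in layout:
            if not isinstance(element, LTTextContainer):
                continue
            chars: list[str] = []
            sizes: list[float] = []
            for line in element:
                if not hasattr(line, "__iter__"):
                    continue
                for obj in line:
                    if isinstance(obj, LTChar):
                        chars.append(obj.get_text())
                        sizes.append(float(obj.size))
                    elif hasattr(obj, "get_text"):
                        # LTAnno: whitespace synthesized by layout analysis
                        chars.append(obj.get_text())
                        sizes.append(sizes[-1] if sizes else 0.0)
            text = "".join(chars)
            if not text.strip():
                continue
            page["blocks"].append(
                {"text": text, "font_sizes": sizes, "bbox": list(element.bbox)}
            )
        pages.append(page)
    return build_document_model(pages)
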