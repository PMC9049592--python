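import pytest

from paperblocks.fixtures import FixtureSpec, generate_article
from paperblocks.templates import GENERIC


@pytest.fixture(scope="session")
def default_article():
    """One deterministic synthetic article (noise + fragmented refs on)."""
    return generate_article(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def generic_template():
    return GENERIC


def make_page(blocks, width=612.0, height=792.0):
    """Assemble a raw page dict for build_document_model."""
    return {"width": width, "height": height, "blocks": blocks}


def make_raw_block(text, size=10.0, bbox=(57.0, 100.0, 300.0, 112.0), sizes=None):
    return {
        "text": text,
        "font_sizes": list(sizes) if sizes is not None else [size] * len(text),
        "bbox": list(bbox),
    }
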