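import pytest

from timecourse_miner import SeriesMetadata
from timecourse_miner.ontology import load_bundled_ontology


@pytest.fixture(scope="session")
def mini_do():
    """The bundled miniature Disease Ontology index."""
    return load_bundled_ontology()


@pytest.fixture
def make_meta():
    """Factory for SeriesMetadata with defaults filled in."""

    def _make(accession="GSE1", **kwargs):
        return SeriesMetadata(accession=accession, **kwargs)

    return _make
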