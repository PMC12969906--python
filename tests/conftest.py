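import pytest

from acescan import popgen
from acescan.genotyping import DEFAULT_REF


@pytest.fixture(scope="session")
def guizhou_tables():
    """The packaged 12-population genotype-count table."""
    return popgen.load_guizhou_counts()


@pytest.fixture(scope="session")
def ref():
    return DEFAULT_REF
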