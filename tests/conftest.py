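import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from minicoi.fixtures import expand_fixture, get_fixture
from minicoi.primers import get_primer


@pytest.fixture(scope="session")
def ml():
    return get_primer("mlCOIintF")


@pytest.fixture(scope="session")
def xt():
    return get_primer("mlCOIintF-XT")


@pytest.fixture(scope="session")
def forward_primers(ml, xt):
    return (ml, xt)


@pytest.fixture(scope="session")
def oithona_regions():
    """The 247 *O. similis* forward-primer regions (lineages x n)."""
    return expand_fixture(get_fixture("oithona_similis"), with_multiplicity=True)


@pytest.fixture(scope="session")
def all_fixture_regions():
    """One region per transcribed table row across all three datasets."""
    out = []
    for name in ("oithona_similis", "appendicularia", "thaliacea"):
        out.extend(expand_fixture(get_fixture(name)))
    return out
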