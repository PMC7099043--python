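import pytest

from mr2sample import harmonize, load_fixture, orient_exposure_positive


@pytest.fixture(scope="session")
def fixture_datasets():
    """The bundled 8-SNP IL-18 exposure / osteoporosis outcome pair."""
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_hset(fixture_datasets):
    """Harmonized, exposure-positive instrument set from the bundled data."""
    exposure, outcome = fixture_datasets
    return orient_exposure_positive(harmonize(exposure, outcome))
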