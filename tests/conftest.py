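import pytest
from hypothesis import settings

from covermix import DEFAULT_SPECIES, reference

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
from covermix.data_model import registry_by_code


@pytest.fixture(scope="session")
def registry():
    return list(DEFAULT_SPECIES)


@pytest.fixture(scope="session")
def by_code(registry):
    return registry_by_code(registry)


@pytest.fixture(scope="session")
def ref_mono():
    """Bundled reference monoculture fits, denormalized."""
    return reference.monoculture_fits()


@pytest.fixture(scope="session")
def ref_bi():
    """Bundled reference biculture fits for all twelve ordered pairs."""
    return reference.biculture_fits()
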