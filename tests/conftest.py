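import pytest

from algadiesel import datasets


@pytest.fixture(scope="session")
def panel():
    """Packaged strain-panel FAME profiles keyed by strain id."""
    return {p.strain_id: p for p in datasets.load_fame_profiles()}


@pytest.fixture(scope="session")
def reference():
    """Published per-strain ADU/LCSF and property values."""
    return datasets.load_reference_properties()


@pytest.fixture(scope="session")
def composition():
    return datasets.load_composition()
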