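import pytest
from hypothesis import settings

from maldiplex.demo import demo_panel, demo_regions

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def panel():
    """Compiled eight-assay demo panel (shared: compilation is deterministic)."""
    return demo_panel()


@pytest.fixture(scope="session")
def regions():
    return {r.accession: r for r in demo_regions()}
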