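import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hybstand import default_interspecific_panel, default_intraspecific_panel

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel():
    """The default 35-locus species-diagnostic panel."""
    return default_interspecific_panel()


@pytest.fixture(scope="session")
def small_panel():
    """A 5-locus diagnostic panel for enumeration-sized tests."""
    return default_interspecific_panel(n_loci=5, panel_id="diag5")


@pytest.fixture(scope="session")
def intra_panels():
    """The two intraspecific panels (35 B loci, 33 D loci)."""
    return default_intraspecific_panel("B"), default_intraspecific_panel("D")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
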