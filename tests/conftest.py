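import pytest
from hypothesis import HealthCheck, settings

import enzyval as ez

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_sets():
    """Bundled replicate certificates: {wine: (automated, manual)}."""
    return ez.load_reference_sets()


@pytest.fixture(scope="session")
def reference_reports(reference_sets):
    """Precision/equivalence block per wine, computed once."""
    return {
        wine: ez.build_precision_report(auto, manual)
        for wine, (auto, manual) in reference_sets.items()
    }


@pytest.fixture
def kit():
    return ez.KitParameters()
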