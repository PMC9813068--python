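import pytest
from hypothesis import settings

from depthfuse import generate_cohort, paper_preset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def training_cohort():
    """One 250/250 training-like synthetic cohort shared across tests."""
    return generate_cohort(paper_preset("training_like", seed=0))
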