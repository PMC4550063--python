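import pytest
from hypothesis import settings

from anginacdss import load_guideline_config

# derandomised hypothesis runs: failures are reproducible in any environment
settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    """The packaged default guideline config (validated at load)."""
    return load_guideline_config()
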