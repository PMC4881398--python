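import pytest
from hypothesis import settings

from cuebind import ModelParams

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def quiet_params():
    """Defaults with activation noise switched off."""
    return ModelParams(noise_scale_s=0.0)
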