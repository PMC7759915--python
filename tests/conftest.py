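import pytest

from bnctkit.synthetic import SyntheticConfig


@pytest.fixture
def synth_config() -> SyntheticConfig:
    """Default generator configuration with a fixed seed."""
    return SyntheticConfig(seed=0)
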