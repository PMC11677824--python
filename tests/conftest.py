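import dataclasses

import pytest

from liposonics import InstrumentPrecision, SyntheticConfig


@pytest.fixture
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=42)


@pytest.fixture
def noiseless_config() -> SyntheticConfig:
    return dataclasses.replace(
        SyntheticConfig(seed=42), precision=InstrumentPrecision(0.0, 0.0, 0.0)
    )
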