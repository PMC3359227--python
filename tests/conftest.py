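import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from posturesim import (
    PopulationConfig,
    ShiftGenParams,
    ShiftRecording,
    generate_population,
)


@pytest.fixture(scope="session")
def toy_shift() -> ShiftRecording:
    """Six-minute shift at 1 sample/min with hand-computable window means."""
    return ShiftRecording("S01", "D1", 1, np.array([0.0, 0.0, 60.0, 60.0, 0.0, 0.0]))


@pytest.fixture(scope="session")
def constant_shift() -> ShiftRecording:
    return ShiftRecording("S01", "D1", 1, np.full(120, 30.0))


@pytest.fixture(scope="session")
def small_population() -> list[ShiftRecording]:
    """12 shifts of 300-330 min: big enough for correlations, fast to sample."""
    config = PopulationConfig(
        composition=((6, 2),),
        duration_range=(300, 330),
        base=ShiftGenParams(),
        seed=42,
    )
    return generate_population(config)
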