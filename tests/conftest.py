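import numpy as np
import pytest

from clonalrhythm import (
    CloneRecord,
    ExpressionSimConfig,
    SimConfig,
    generate_expression_panel,
    spread_clone_panel,
)


@pytest.fixture
def default_config() -> SimConfig:
    return SimConfig(seed=42)


@pytest.fixture
def noiseless_config() -> SimConfig:
    """Trace generator without photon noise or baseline drift."""
    return SimConfig(noise_cv=0.0, trend_decay=0.0, seed=42)


@pytest.fixture
def reference_clone() -> CloneRecord:
    return CloneRecord("ref", 0, None, 24.6, 24.6)


@pytest.fixture
def clone_panel() -> list[CloneRecord]:
    return spread_clone_panel(25)


@pytest.fixture
def expression_panel(clone_panel):
    return generate_expression_panel(clone_panel, ExpressionSimConfig(), seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
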