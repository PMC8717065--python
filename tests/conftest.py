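import numpy as np
import pytest

from crewrisk import ScenarioConfig, fixture_config


@pytest.fixture
def tiny_config() -> ScenarioConfig:
    """A 4x3 crew over 12 days with 3 replicates: fast but non-degenerate."""
    return ScenarioConfig(
        n_workers=12, n_cols=4, n_rows=3, n_days=12, replicates=3,
        steady_window=5, master_seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def team6_config() -> ScenarioConfig:
    return fixture_config(6)
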