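import numpy as np
import pytest

from famap.food_availability import EnergyConversionTable, MAEWeights


@pytest.fixture(scope="session")
def energy_table() -> EnergyConversionTable:
    return EnergyConversionTable.default()


@pytest.fixture(scope="session")
def mae_weights() -> MAEWeights:
    return MAEWeights.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_scene():
    """A coarse, quick synthetic scene shared across tests."""
    from famap.synthetic import SceneConfig, generate_scene, _default_indicators

    indicators = _default_indicators()
    cfg = SceneConfig(n_ea=40, households_per_ea=6, resolution_deg=0.25,
                      indicators={k: indicators[k] for k in ("banana", "beans")})
    return generate_scene(cfg, seed=7), cfg
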