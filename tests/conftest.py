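import logging

import numpy as np
import pytest

from regnet.simulate import Bundle, PlantedEffect, SimulationConfig, build_bundle

logging.getLogger("regnet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_bundle() -> Bundle:
    """A compact default-noise bundle with one planted enhancer driver."""
    cfg = SimulationConfig(
        n_genes=10,
        n_background_genes=200,
        planted_effects=[PlantedEffect("VEN04", "cre_accessibility", 4.0)],
    )
    return build_bundle(cfg, seed=11)


@pytest.fixture(scope="session")
def null_bundle() -> Bundle:
    """A bundle with no planted effects and default noise."""
    return build_bundle(SimulationConfig(n_genes=10, n_background_genes=200), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
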