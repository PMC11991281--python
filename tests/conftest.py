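import numpy as np
import pytest

import teaphys as tp


@pytest.fixture(scope="session")
def mi_scene():
    """Separable 5-band scene with ground-truth canopy mask."""
    return tp.generate_scene(0.6, size_px=(128, 128), seed=11)


@pytest.fixture(scope="session")
def rgb_scene():
    return tp.generate_scene(0.6, tp.SpectraConfig(family="CI"), size_px=(96, 96), seed=11)


@pytest.fixture(scope="session")
def planted_table():
    """500 DSZs, 2 causal + 20 noise features, SNR ~ 2 (the default planted
    model); returns (table, truth)."""
    return tp.generate_feature_table(500, 20, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
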