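import numpy as np
import pytest

from bdnet import NoiseParams, PairedSample, generate_phantom, simulate_level


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom64():
    return generate_phantom(64, 64, n_cells=5, membrane_contrast=0.8, seed=7)


@pytest.fixture(scope="session")
def small_pairs():
    """Twelve 64×64 paired samples at mixed levels/modalities."""
    params = NoiseParams(alpha=80.0, sigma=0.02)
    pairs = []
    for i in range(12):
        clean = generate_phantom(64, 64, n_cells=4, membrane_contrast=0.6, seed=200 + i)
        level = (1, 4)[i % 2]
        noisy = simulate_level(clean, params, level=level, seed=300 + i)
        tag = ("confocal", "widefield")[i % 2]
        pairs.append(PairedSample(noisy, clean, level, tag))
    return pairs
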