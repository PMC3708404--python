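import numpy as np
import pytest

import ltcvol as lv


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def planted_ensemble():
    """Noiseless ensemble with three orthogonal planted rank-one bases.

    Generated without class structure so that greedy extraction must
    recover exactly the planted bases; ground truth rides along.
    """
    spec = lv.SynthSpec(
        shape=(10, 9, 8),
        n_samples=12,
        n_shared_bases=3,
        n_class_bases=0,
        base_sigma=5.0,
        spectrum_decay=0.6,
        noise_sigma=0.0,
        mean_level=0.0,
        mean_amplitude=0.0,
        seed=7,
    )
    return lv.generate(spec)


@pytest.fixture(scope="session")
def noisy_ensemble():
    """Small noisy ensemble with a class-linked basis, for end-to-end tests."""
    spec = lv.SynthSpec(
        shape=(12, 10, 8),
        n_samples=16,
        n_shared_bases=4,
        n_class_bases=1,
        base_sigma=8.0,
        spectrum_decay=0.7,
        class_effect=3.0,
        class_sigma=0.3,
        noise_sigma=0.2,
        mean_level=50.0,
        seed=11,
    )
    return lv.generate(spec)


def random_unit(rng, n):
    v = rng.standard_normal(n)
    return v / np.linalg.norm(v)
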