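import numpy as np
import pytest

from transportscreen import DMPNNConfig, FixtureSpec, generate_motif_dataset


@pytest.fixture(scope="session")
def small_motif_dataset():
    """80-compound noise-free motif dataset for fast unit tests."""
    return generate_motif_dataset(FixtureSpec(n_compounds=80, seed=11))


@pytest.fixture(scope="session")
def tiny_config():
    """Down-scaled network for unit tests exercising mechanics, not accuracy."""
    return DMPNNConfig(
        hidden_size=16, depth=2, epochs=4, ensemble_size=2, batch_size=25, seed=3
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_fingerprint(rng, width=128, max_bits=40):
    from transportscreen import Fingerprint

    n = int(rng.integers(0, max_bits + 1))
    bits = frozenset(int(b) for b in rng.choice(width, size=n, replace=False))
    return Fingerprint(bits=bits, width=width, radius=2)
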