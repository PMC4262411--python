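import numpy as np
import pytest

from ffavarsel.preprocess import kennard_stone_split
from ffavarsel.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_planted():
    """Small planted-support dataset + Kennard-Stone split for search tests.

    30 candidate variables, 3 informative, mild noise: large enough that
    selection is non-trivial, small enough that a short firefly run
    converges in seconds.
    """
    spec = SyntheticSpec(
        n_samples=150, n_variables=30, support=(4, 11, 23), noise_frac=0.05, seed=42
    )
    data, spec = generate(spec)
    split = kennard_stone_split(data.X, (80, 35, 35))
    return data, spec, split


@pytest.fixture(scope="session")
def tiny_planted_noiseless():
    """Noiseless planted data: the support reproduces y exactly."""
    spec = SyntheticSpec(
        n_samples=60, n_variables=12, support=(2, 7, 9), noise_frac=0.0, seed=11
    )
    data, spec = generate(spec)
    split = kennard_stone_split(data.X, (30, 15, 15))
    return data, spec, split
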