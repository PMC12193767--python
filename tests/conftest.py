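import numpy as np
import pytest
from hypothesis import settings

from cwqsar import FixtureSpec, default_true_weights, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """60 short synthetic molecules with known ground truth, light noise."""
    spec = FixtureSpec(
        n_molecules=60, noise_sd=0.1, seed=11,
        true_weights=default_true_weights(seed=11),
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def recovery_spec():
    """The standard parameter-recovery fixture recipe (n=400, noise 0.2)."""
    def make(seed: int) -> FixtureSpec:
        return FixtureSpec(
            n_molecules=400, noise_sd=0.2, seed=seed,
            true_weights=default_true_weights(seed=seed),
        )
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
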