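import numpy as np
import pytest

from prepostsim import (
    TrueModelSpec,
    apply_noise,
    calibrate_true_effects,
    generate_true_dataset,
)


@pytest.fixture(scope="session")
def spec():
    return TrueModelSpec()


@pytest.fixture(scope="session")
def effects(spec):
    return calibrate_true_effects(spec)


@pytest.fixture(scope="session")
def large_truth(effects, spec):
    """One million noise-free subjects for law-of-large-numbers checks."""
    return generate_true_dataset(effects, spec, 1_000_000, 20260920)


@pytest.fixture()
def small_observed(effects, spec):
    """A single modest observed study (n=80, reliability .80)."""
    truth = generate_true_dataset(effects, spec, 80, 7)
    return apply_noise(truth, 0.80, 8)


def random_observed(effects, spec, rng, n=None, reliability=None):
    """Helper shared by the identity/equivalence property tests."""
    n = n or 2 * int(rng.integers(8, 30))
    reliability = reliability or float(rng.uniform(0.5, 1.0))
    truth = generate_true_dataset(effects, spec, n, rng)
    return apply_noise(truth, reliability, rng)


@pytest.fixture(scope="session")
def rng_factory():
    def make(seed):
        return np.random.default_rng(seed)

    return make
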