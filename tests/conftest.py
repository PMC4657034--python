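import numpy as np
import pytest
from dataclasses import replace

from flyvep.synth import default_presets, simulate_cohort


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture(scope="session")
def control_spec(presets):
    return presets["w1118"]


@pytest.fixture(scope="session")
def noiseless_spec(control_spec):
    return replace(control_spec, noise_amp=0.0, fly_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_spec):
    """Tiny noise-free cohort: features must equal the generating surface."""
    return simulate_cohort([noiseless_spec], n_flies=2, n_reps=2, seed=11)


@pytest.fixture(scope="session")
def small_noisy_cohort(control_spec):
    spec = replace(control_spec, name="ctrlA")
    return simulate_cohort([spec], n_flies=3, n_reps=3, seed=5)


def gaussian_two_class(seed, n_per=15, p=8, shift=0.0):
    """Balanced two-class Gaussian data; shift moves the second class."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, p))
    X[n_per:] += shift
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


@pytest.fixture
def two_class_separable():
    return gaussian_two_class(seed=0, n_per=15, p=8, shift=6.0)
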