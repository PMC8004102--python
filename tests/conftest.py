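"""Shared fixtures: the ground-truth model and synthetic datasets."""

import numpy as np
import pytest

import onoffslide as oos
from onoffslide.fitting import FitConfig


@pytest.fixture(scope="session")
def space():
    return oos.build_configuration_space()


@pytest.fixture(scope="session")
def catalog():
    return oos.build_process_catalog()


@pytest.fixture(scope="session")
def best_model():
    """The best-supported model structure: regulated global assembly plus
    constitutive D, D1-4, S2* and S3-4."""
    return oos.ModelSpec.make(("A", "D", "D1-4", "S2*", "S3-4"), ("A",))


@pytest.fixture(scope="session")
def ground_truth():
    return oos.make_reference_fixture(seed=3)


@pytest.fixture(scope="session")
def synthetic_data(ground_truth):
    """One deterministic draw of all three dataset types."""
    rng = ground_truth.rng()
    counts = oos.sample_config_counts(ground_truth, rng)
    fc = oos.sample_foldchanges(ground_truth, rng)
    ex = oos.sample_exchange(ground_truth, rng)
    return counts, fc, ex


@pytest.fixture(scope="session")
def quick_fit_config():
    """Few multi-starts: enough for the smooth, low-dimensional test problems."""
    return FitConfig(n_starts=4, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
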