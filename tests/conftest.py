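import numpy as np
import pytest

from mixirt.model import ParameterSet, QuadratureGrid
from mixirt.simulate import generate_responses, scenario_preset


@pytest.fixture(scope="session")
def grid21():
    return QuadratureGrid.gauss_hermite(21)


@pytest.fixture(scope="session")
def ordered_item():
    """Ordinary 11-category item: ordered equidistant thresholds, slope 1.5."""
    return scenario_preset("ordered_11")


@pytest.fixture(scope="session")
def avoided_item():
    """11-category item with thresholds 7/8 reversed (category 7 avoided)."""
    return scenario_preset("avoided_mid")


@pytest.fixture(scope="session")
def small_mixture():
    """Well-separated 2-class mixture on two 3-category items."""
    return ParameterSet(
        thresholds=np.array(
            [[[-1.5, 0.0], [-0.5, 1.0]], [[1.0, 2.0], [0.5, 2.5]]]
        ),
        discriminations=np.ones((2, 2)),
        mixing=np.array([0.6, 0.4]),
        variances=np.array([1.0, 1.0]),
        category_counts=np.array([3, 3]),
    )


@pytest.fixture(scope="session")
def small_mixture_data(small_mixture):
    data, truth = generate_responses(small_mixture, 400, seed=7)
    return data, truth


@pytest.fixture(scope="session")
def hilda_params():
    return scenario_preset("hilda_like")


@pytest.fixture(scope="session")
def hilda_stable_params():
    return scenario_preset("hilda_like_stable")
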