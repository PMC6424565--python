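import numpy as np
import pytest

from cdfit.density_model import AtomicModel, SpreadParams
from cdfit.fixtures import FixtureSpec, make_ground_truth_maps, make_toy_polymer
from cdfit.map_io import DensityMap


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def polymer(fixture_spec):
    return make_toy_polymer(fixture_spec)


@pytest.fixture(scope="session")
def maps(polymer, fixture_spec):
    model, _ = polymer
    full, half1, half2, truth = make_ground_truth_maps(model, fixture_spec)
    return {"full": full, "half1": half1, "half2": half2, "truth": truth}


@pytest.fixture
def random_map():
    rng = np.random.default_rng(42)
    return DensityMap(rng.standard_normal((12, 10, 8)), (1.5, 2.0, 2.5), (1.0, -3.0, 2.0))


@pytest.fixture
def uniform_params():
    return SpreadParams(sigma=0.2, weight_mode="uniform")
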