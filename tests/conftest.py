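import numpy as np
import pytest

from twosfca.pipeline import run_pipeline
from twosfca.synthetic_province import (
    ProvinceSpec,
    generate_province,
    known_answer_scenario,
)


@pytest.fixture(scope="session")
def scenario():
    return known_answer_scenario()


@pytest.fixture(scope="session")
def scenario_result(scenario):
    return run_pipeline(scenario)


@pytest.fixture(scope="session")
def province_spec7():
    # ~500 fishnet cells, 25 facilities: the standard mid-size fixture
    return ProvinceSpec(
        seed=7,
        extent=(0.0, 0.0, 46000.0, 44000.0),
        n_admin_units=6,
        n_facilities=25,
    )


@pytest.fixture(scope="session")
def province7(province_spec7):
    return generate_province(province_spec7)


@pytest.fixture(scope="session")
def province7_result(province7):
    return run_pipeline(province7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
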