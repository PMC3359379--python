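import numpy as np
import pytest

from leafalloc import (
    COLLATZ,
    DEFAULT_NUE,
    Environment,
    PlantTraits,
)
from leafalloc.experiments import sensitivity_control_env, table3_traits


@pytest.fixture(scope="session")
def kinetics():
    return COLLATZ


@pytest.fixture(scope="session")
def nue():
    return DEFAULT_NUE


@pytest.fixture(scope="session")
def control_env():
    return sensitivity_control_env()


@pytest.fixture(scope="session")
def pfts():
    return table3_traits()


@pytest.fixture(scope="session")
def evergreen(pfts):
    return pfts["evergreen"]


def random_traits(rng: np.random.Generator) -> PlantTraits:
    """A random but physiologically plausible trait set."""
    return PlantTraits(
        lma=float(rng.uniform(40.0, 140.0)),
        leaf_n=float(rng.uniform(0.008, 0.035)),
        f_s=float(rng.uniform(0.2, 0.95)),
        d_ns=float(rng.uniform(2.0, 120.0)),
        f_cleaf=float(rng.uniform(0.1, 0.7)),
    )


def random_environment(rng: np.random.Generator) -> Environment:
    day_t = float(rng.uniform(5.0, 30.0))
    return Environment(
        par=float(rng.uniform(200.0, 1500.0)),
        co2_ppm=float(rng.uniform(300.0, 700.0)),
        day_temp=day_t,
        night_temp=day_t - float(rng.uniform(0.0, 10.0)),
        rh=float(rng.uniform(0.4, 1.0)),
        day_hours=float(rng.uniform(10.0, 16.0)),
    )
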