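import numpy as np
import pytest

from invaroute.coalsim import Genealogy, SampleConfig, simulate_dataset
from invaroute.demography import (
    ParameterDraw,
    build_builtin_scenario,
    sample_parameters,
)


@pytest.fixture(scope="session")
def scenario1():
    return build_builtin_scenario("scenario1")


@pytest.fixture(scope="session")
def scenario2():
    return build_builtin_scenario("scenario2")


@pytest.fixture(scope="session")
def truth_draw():
    return ParameterDraw(
        values={
            "t1": 75.0,
            "t2": 100.0,
            "t3": 200.0,
            "r": 0.5,
            "micro_mean_mu": 5e-4,
            "mt_mu": 1e-6,
        },
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cfg(scenario1):
    return SampleConfig.uniform(scenario1.sampled_populations, 10, 6)


@pytest.fixture(scope="session")
def small_dataset(scenario1, truth_draw, small_cfg):
    return simulate_dataset(scenario1, truth_draw, small_cfg, 2024)


def star_genealogy(n_tips: int, depth: float) -> Genealogy:
    """A star tree: every tip hangs directly off a root at ``depth``.

    Not a binary coalescent tree, but a valid branch structure for the
    mutation overlays (used as an independent oracle geometry).
    """
    parent = np.full(n_tips + 1, n_tips, dtype=np.int32)
    parent[n_tips] = -1
    time = np.zeros(n_tips + 1)
    time[n_tips] = depth
    return Genealogy(n_tips, parent, time)


def two_tip_genealogy(tmrca: float) -> Genealogy:
    parent = np.array([2, 2, -1], dtype=np.int32)
    time = np.array([0.0, 0.0, tmrca])
    return Genealogy(2, parent, time)
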