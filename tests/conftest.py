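import pytest

import corechemostat as cc
from corechemostat.synthetic_data import benchmark_truth


@pytest.fixture(scope="session")
def bioreactor_community():
    return cc.builtin_community("bioreactor")


@pytest.fixture(scope="session")
def bioreactor_sim(bioreactor_community):
    """The baseline 35-day bioreactor-mimic simulation (shared: ~1 s)."""
    scenario = cc.build_scenario("bioreactor")
    return cc.simulate(scenario, bioreactor_community)


@pytest.fixture(scope="session")
def nearly_invivo_sim():
    """The 35-day nearly-in-vivo run: two strains per group, microbial inflow."""
    scenario = cc.build_scenario("nearly_invivo", seed=3)
    return cc.simulate(scenario)


@pytest.fixture(scope="session")
def benchmark():
    """(community, scenario, truth simulation) of the 3-group benchmark world."""
    return benchmark_truth(0)
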