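import numpy as np
import pytest

from rcfopt.core import FacilityConfiguration, size_beds_to_demand
from rcfopt.synthetic import ScenarioSpec, generate_scenario, micro_instance


@pytest.fixture(scope="session")
def m1():
    """The 2x2 worked-example instance (demands 10/20, crossed distances)."""
    return micro_instance()


@pytest.fixture(scope="session")
def m1_nearest(m1):
    """M1 with both sites open, beds sized to demand (10, 20)."""
    return size_beds_to_demand(m1, [0, 1])


@pytest.fixture(scope="session")
def m1_beds_15_30(m1, m1_nearest):
    """M1 with both sites open and beds (15, 30) — the accessibility example."""
    return FacilityConfiguration(
        open=np.array([1, 1]),
        beds=np.array([15.0, 30.0]),
        allocation=m1_nearest.allocation,
        p=2,
    )


@pytest.fixture(scope="session")
def district():
    """A default synthetic district with its planted current configuration."""
    return generate_scenario(ScenarioSpec(seed=11))


def random_instance_config(seed, n_centers=8, n_sites=6, p=3):
    """A small random instance and a demand-sized configuration (helper)."""
    spec = ScenarioSpec(
        seed=seed, n_centers=n_centers, n_sites=n_sites,
        n_existing=min(p, n_sites), extent=2000.0, n_clusters=2, elderly_mu=6.0,
    )
    instance, _ = generate_scenario(spec)
    rng = np.random.default_rng(seed + 77)
    open_sites = np.sort(rng.choice(n_sites, size=p, replace=False))
    return instance, size_beds_to_demand(instance, open_sites)
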