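import numpy as np
import pandas as pd
import pytest

from teleaccess import (
    CostMatrix,
    DemandDivision,
    Instance,
    SupplySite,
    Tier,
    make_fixture_suite,
)


@pytest.fixture(scope="session")
def suite():
    return make_fixture_suite(seed=0)


@pytest.fixture(scope="session")
def toy(suite):
    """Hand-calculable instance: S=12, M=(100, 200), d=(1, 2)."""
    return suite["two_division_toy"].instance


@pytest.fixture(scope="session")
def uniform(suite):
    return suite["uniform"].instance


@pytest.fixture(scope="session")
def lubei_like(suite):
    return suite["lubei_like"].instance


def random_instance(
    rng: np.random.Generator,
    n_div: int = 5,
    n_comm: int = 4,
    n_tert: int = 2,
    rho: float = 0.4,
) -> Instance:
    """Small random instance with explicit positive distances (no geometry)."""
    divisions = [
        DemandDivision(
            id=f"k{i}",
            pop_total=float(rng.uniform(500, 5000)),
            pop_elderly=float(rng.uniform(100, 2000)),
            pop_chronic=float(rng.uniform(50, 2000)),
        )
        for i in range(n_div)
    ]
    sites = [
        SupplySite(id=f"c{j}", tier=Tier.community, resource_offline=float(rng.uniform(10, 300)))
        for j in range(n_comm)
    ] + [
        SupplySite(
            id=f"t{j}",
            tier=Tier.tertiary_A,
            resource_offline=float(rng.uniform(200, 3000)),
            online_cap_fraction=rho,
        )
        for j in range(n_tert)
    ]
    d = rng.uniform(0.5, 20.0, (len(sites), n_div))
    costs = CostMatrix(
        pd.DataFrame(d, index=[s.id for s in sites], columns=[dv.id for dv in divisions])
    )
    return Instance(divisions, sites, costs, coord_mode="planar")
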