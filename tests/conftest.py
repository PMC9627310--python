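import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from bym2map import (  # noqa: E402
    FitConfig,
    build_queen_adjacency,
    fit_bym2,
    make_lattice,
    make_spec,
)
from bym2map.standardize import area_summary  # noqa: E402
from bym2map.synthetic import SyntheticScenario, simulate_registry  # noqa: E402


@pytest.fixture(scope="session")
def lattice3():
    return make_lattice(3, 3, 0)


@pytest.fixture(scope="session")
def graph3(lattice3):
    return build_queen_adjacency(lattice3)


@pytest.fixture(scope="session")
def graph6():
    return build_queen_adjacency(make_lattice(6, 6, 0))


@pytest.fixture(scope="session")
def graph_with_island():
    return build_queen_adjacency(make_lattice(3, 3, 1))


@pytest.fixture(scope="session")
def small_counts() -> pd.DataFrame:
    """2 areas x 2 strata hand table used across standardization tests."""
    return pd.DataFrame(
        {
            "area_id": ["A", "A", "B", "B"],
            "age_group": ["young", "old", "young", "old"],
            "cases": [2, 8, 4, 10],
            "person_years": [50.0, 200.0, 150.0, 100.0],
        }
    )


@pytest.fixture(scope="session")
def wellspec_fit():
    """A well-specified moderate-size fit shared by summary/check tests.

    10x10 lattice, E ~ 50 per area, true (phi, sigma) = (0.5, 0.4); 2 chains
    of 300 kept draws. Returns (scenario, graph, sir table, spec, samples,
    truth).
    """
    sc = SyntheticScenario(
        nx=10, ny=10, phi_true=0.5, sigma_true=0.4,
        pop_range=(11_000, 14_000), seed=42,
    )
    areas, data, truth = simulate_registry(sc)
    graph = build_queen_adjacency(areas)
    sir = area_summary(data).reindex(graph.nodes)
    spec = make_spec(sir["observed"].to_numpy(), sir["expected"].to_numpy(), graph)
    samples = fit_bym2(spec, FitConfig(chains=2, warmup=300, samples=300, seed=7))
    return sc, graph, sir, spec, samples, truth


@pytest.fixture(scope="session")
def tiny_fit():
    """A fast 4x4 fit for API-level tests that just need valid samples."""
    sc = SyntheticScenario(nx=4, ny=4, phi_true=0.4, sigma_true=0.4,
                           pop_range=(5_000, 10_000), seed=3)
    areas, data, truth = simulate_registry(sc)
    graph = build_queen_adjacency(areas)
    sir = area_summary(data).reindex(graph.nodes)
    spec = make_spec(sir["observed"].to_numpy(), sir["expected"].to_numpy(), graph)
    samples = fit_bym2(spec, FitConfig(chains=2, warmup=250, samples=250, seed=5))
    return graph, sir, spec, samples


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
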