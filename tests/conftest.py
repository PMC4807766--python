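import numpy as np
import pytest

from scenoset.fixtures import (VirtualSpeciesSpec, make_baseline_grid,
                               make_virtual_species, table2_fixture)
from scenoset.scenario_io import ScenarioDelta, ScenarioTable


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()


@pytest.fixture(scope="session")
def small_grid():
    return make_baseline_grid(400, rng_seed=0)


@pytest.fixture(scope="session")
def species(small_grid):
    return make_virtual_species(small_grid, VirtualSpeciesSpec(rng_seed=0))


def make_table(deltas: np.ndarray, variables=None) -> ScenarioTable:
    """A scenario table from a bare delta matrix, with generated ids."""
    deltas = np.atleast_2d(np.asarray(deltas, dtype=float))
    variables = variables or [f"d{v}" for v in range(deltas.shape[1])]
    scenarios = [
        ScenarioDelta(f"CTR{i}", f"M{i}", "A2",
                      dict(zip(variables, row)))
        for i, row in enumerate(deltas)
    ]
    return ScenarioTable(scenarios, list(variables))
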