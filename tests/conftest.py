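import numpy as np
import pandas as pd
import pytest

import bayescount as bc


@pytest.fixture(scope="session")
def small_design():
    return bc.SimulationDesign(
        n_regions=5,
        groups=["A", "B"],
        animals_per_group=4,
        seed=7,
        tau_truth=0.1,
        base_log_count=5.0,
        group_effects=[0.0, -0.5],
    )


@pytest.fixture(scope="session")
def small_table(small_design):
    table, truth = bc.simulate(small_design)
    return table, truth


@pytest.fixture(scope="session")
def small_fit(small_table):
    """Poisson/normal fit of the small synthetic dataset, shared by tests."""
    table, truth = small_table
    draws = bc.fit(
        table,
        bc.ModelConfig(),
        bc.SamplerConfig(chains=2, iterations_per_chain=800, seed=3),
    )
    return table, truth, draws


@pytest.fixture(scope="session")
def tiny_table():
    design = bc.SimulationDesign(
        n_regions=2,
        groups=["A", "B"],
        animals_per_group=3,
        seed=5,
        tau_truth=0.1,
        base_log_count=3.5,
        pi_truth=0.1,
    )
    return bc.simulate(design)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def one_cell_table():
    """Single region, single group, unit areas: the conjugate-style oracle
    configuration."""
    y = [3, 7, 5, 4, 6, 2]
    df = pd.DataFrame(
        {
            "count": y,
            "region": "R1",
            "group": "G1",
            "animal": [f"a{i}" for i in range(len(y))],
            "area": 1.0,
        }
    )
    return bc.CellCountTable.from_frame(df)
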