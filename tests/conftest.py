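import numpy as np
import pytest

from labopt import (
    CandidateSet,
    FrontierBatchOptimizer,
    SweepSpec,
    generate_sweep,
    objective_series,
)
from labopt.fixtures import sweep_space
from labopt.optimizer import TabularOracle


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def bowl_sweep():
    """A 120-row unimodal sweep table with its answer key and space."""
    spec = SweepSpec(grid_sizes=(5, 4, 3, 2), family="bowl")
    df, key = generate_sweep(spec, seed=1)
    return df, key, sweep_space(spec)


@pytest.fixture(scope="session")
def bumps_sweep():
    """A 120-row multimodal sweep table with its answer key and space."""
    spec = SweepSpec(grid_sizes=(5, 4, 3, 2), family="bumps")
    df, key = generate_sweep(spec, seed=1)
    return df, key, sweep_space(spec)


def make_tabular_optimizer(df, space, objective="height", k=4, budget=25, **kw):
    values = objective_series(df, objective)
    candidates = CandidateSet.from_dataframe(df, space)
    oracle = TabularOracle(candidates, values)
    return FrontierBatchOptimizer(oracle, dim=space.dim, k=k, budget=budget, **kw)


@pytest.fixture
def tabular_optimizer_factory():
    return make_tabular_optimizer
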