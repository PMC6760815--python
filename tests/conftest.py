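import itertools

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")

from treesweep import (
    DemographicModel,
    FrequencyGrid,
    SelectionModel,
    TimeGrid,
    TransitionCache,
)
from treesweep.hmm import emission_log_matrix
from treesweep.simulate import SimCondition, simulate_replicate

SEED = 20260927


@pytest.fixture(scope="session")
def cache():
    return TransitionCache()


@pytest.fixture(scope="session")
def small_grid():
    return TimeGrid((0.0, 50.0, 200.0, 1000.0, 60000.0))


@pytest.fixture(scope="session")
def small_demog(small_grid):
    return DemographicModel.constant(300.0, small_grid)


@pytest.fixture(scope="session")
def small_fg():
    return FrequencyGrid.default(6)


def make_toy_replicate(rng, d=5, K=4, n_der=3, n_anc=2, N=300.0, s=0.0):
    """A tiny simulated replicate on a coarse grid, for brute-force oracles."""
    horizon = 100.0 * 2.0 * N
    inner = np.geomspace(30.0, horizon, K)
    grid = TimeGrid((0.0,) + tuple(np.unique(np.round(inner))))
    demog = DemographicModel.constant(N, grid)
    fg = FrequencyGrid.default(d)
    x0 = fg.x[rng.integers(2, d - 1)]
    cond = SimCondition(demog, fg, x0, SelectionModel(s), n_der, n_anc)
    return simulate_replicate(cond, rng), cond


def enumerate_joint(E, tsets, init):
    """Brute-force sum of P(C, X) over every trajectory ending in origination.

    Independent of the recursion implementation: loops over all d^K paths in
    plain Python, multiplying initialization, transition, and emission terms.
    Returns (total probability, per-epoch-state posterior numerators).
    """
    K, d = E.shape
    Eprob = np.exp(E)
    total = 0.0
    marg = np.zeros((K, d))
    for path in itertools.product(range(d), repeat=K):
        if path[-1] != 0:
            continue
        p = init[path[0]]
        for i in range(K - 1):
            p *= tsets[i][path[i], path[i + 1]]
        for i in range(K):
            p *= Eprob[i, path[i]]
        if p > 0:
            total += p
            for i in range(K):
                marg[i, path[i]] += p
    return total, marg
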