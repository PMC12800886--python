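import numpy as np
import pandas as pd
import pytest

import grazenet as g
from grazenet.simulate import DEFAULT_GRAZERS

GRAZERS = list(DEFAULT_GRAZERS)


def _asv_ids(n):
    return [f"ASV{i + 1:04d}" for i in range(n)]


def zero_truth(n_asv):
    z = pd.DataFrame(0.0, index=GRAZERS, columns=_asv_ids(n_asv))
    return g.TruthTable(delta_ti=z.copy(), delta_nti=z.copy())


def sparse_pm1_truth(n_asv, rng, sparsity=0.10):
    """±1 log-effects on a `sparsity` fraction of (grazer, ASV) pairs."""

    def one():
        m = (rng.random((len(GRAZERS), n_asv)) < sparsity) * np.where(
            rng.random((len(GRAZERS), n_asv)) < 0.5, -1.0, 1.0
        )
        return pd.DataFrame(m, index=GRAZERS, columns=_asv_ids(n_asv))

    return g.TruthTable(delta_ti=one(), delta_nti=one())


@pytest.fixture(scope="session")
def null_fit():
    """Zero-effect experiment (300 pairs/mode) and its fitted results."""
    truth = zero_truth(60)
    exp = g.simulate_experiment(g.SimulationConfig(n_asv=60, seed=11), truth=truth)
    res = g.DynamicIndexModel(exp.counts, exp.metadata, n_boot=999, seed=3).fit()
    return exp, res


@pytest.fixture(scope="session")
def recovery_fit():
    """±1-effect experiment at full design depth and its fitted results."""
    rng = np.random.default_rng(5)
    truth = sparse_pm1_truth(100, rng)
    exp = g.simulate_experiment(g.SimulationConfig(n_asv=100, seed=21), truth=truth)
    res = g.DynamicIndexModel(exp.counts, exp.metadata, n_boot=999, seed=4).fit()
    return exp, res


@pytest.fixture(scope="session")
def small_experiment():
    """Small default-truth experiment for plumbing tests."""
    return g.simulate_experiment(n_asv=30, seed=7, effect_sparsity=0.15)
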