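"""Shared fixtures: the expensive training runs are session-scoped so several
tests (learning-curve checks, metric properties, acceptance tests) can assert
against a single simulation ensemble."""

from __future__ import annotations

import numpy as np
import pytest

from olfbayes.bulb import SimConfig
from olfbayes.experiments import (pooled_correlation, run_go_nogo_experiment,
                                  train_sparse_coding, train_unsupervised)

# Desk-scale integration profile for the long training ensembles: steady
# states are integrator-independent, and at these tolerances the residual
# rate error is far below the sigma_x = 1 sensory noise.
DESK = dict(dt=4.0, T_max=3000.0, steady_tol=5e-5, dyn_dtype="float32")

SMALL_SEEDS = 11
SMALL = dict(M=20, N=100, c_o=0.15)
SMALL_TRIALS = 1500


@pytest.fixture(scope="session")
def small_runs():
    """5-seed ensemble of the bulb circuit at the desk-scale condition
    (M=20, N=100, c_o=0.15, 1500 trials), with learning-curve metrics."""
    config = SimConfig(**SMALL, **DESK)
    res = train_unsupervised(config, seed=SMALL_SEEDS, n_trials=SMALL_TRIALS,
                             n_sims=5, eval_window=100, metric_every=100)
    res["correlation"] = pooled_correlation(res["estimates"], res["truths"])
    return res


@pytest.fixture(scope="session")
def sc_runs():
    """Sparse-coding baseline on the matched worlds (same seed => same
    mixing matrices), one run per learning rate, 5 seeds each."""
    out = {}
    config = SimConfig(**SMALL, **DESK)
    for eta_w in (0.3, 0.5, 1.0):
        out[eta_w] = train_sparse_coding(
            config, seed=SMALL_SEEDS, n_trials=SMALL_TRIALS, n_sims=5,
            eta_w=eta_w, max_steps=10_000, grad_tol=1e-4)
    return out


@pytest.fixture(scope="session")
def gonogo_run():
    """Go/no-go pipeline at the study condition (M=50, N=200, feedback
    variant), 50 simulations, desk-scale pretraining."""
    config = SimConfig(M=50, N=200, **DESK)
    return run_go_nogo_experiment(seed=5, n_sims=50, n_pretrain=2000,
                                  n_reward_trials=20, config=config)


@pytest.fixture(scope="session")
def variant_runs():
    """Circuit variants a-c trained on matched seeds for the ordering check."""
    out = {}
    config = SimConfig(**SMALL, **DESK)
    for variant in ("bayes_copy", "local", "local_lateral"):
        res = train_unsupervised(config, seed=3, n_trials=500, n_sims=3,
                                 variant=variant, eval_window=100,
                                 decode_pbar=True)
        res["correlation"] = pooled_correlation(res["estimates"], res["truths"])
        out[variant] = res
    return out


@pytest.fixture(scope="session")
def sparseness_runs():
    """Short runs at the lifetime-sparseness condition (M=100, N=400,
    Z_rho=0.3, ~300 stimuli), 5 seeds."""
    config = SimConfig(M=100, N=400, c_o=0.03, Z_rho=0.3, **DESK)
    return train_unsupervised(config, seed=17, n_trials=300, n_sims=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
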