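"""Shared fixtures.

The expensive artifacts — one scaled co-evolution run and its paired
trained/random evaluation episodes — are built once per session and shared
by the ecosystem-level tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import predprey as pp
from predprey.policies import RandomPolicy

# The scaled study condition: a 30x30 torus with area-proportional
# populations (36 predators, 180 prey keep the 4%/20% densities of the
# full 50x50 / 100 / 500 setting), 600-step evaluation episodes.
SCALED_ENV = pp.EnvConfig(N=30, nX=36, nY=180, max_steps=600)
EVAL_SEEDS = (101, 102, 103, 104, 105)
BURN_IN = 150


@pytest.fixture(scope="session")
def trained_policies():
    """Co-evolved policies at the scaled condition (10 outer iterations)."""
    cfg = pp.TrainConfig(n_iterations=10, seed=7)
    pol_pred, pol_prey, history = pp.coevolve(SCALED_ENV, cfg)
    assert len(history) == 10
    return pol_pred, pol_prey


def _evaluate(policies, seeds):
    out = []
    for seed in seeds:
        series, snaps = pp.run_episode(policies, SCALED_ENV, seed,
                                       snapshot_steps=(SCALED_ENV.max_steps,))
        burn = min(BURN_IN, len(series) - 1)
        summary = pp.summarize(series, burn_in=burn)
        out.append({"series": series, "summary": summary,
                    "final_state": snaps.get(SCALED_ENV.max_steps)})
    return out


@pytest.fixture(scope="session")
def trained_runs(trained_policies):
    """Five evaluation episodes of the trained policy pair."""
    return _evaluate(trained_policies, EVAL_SEEDS)


@pytest.fixture(scope="session")
def random_runs():
    """Paired (same seeds) evaluation episodes of uniform-random policies."""
    return _evaluate((RandomPolicy("predator"), RandomPolicy("prey")),
                     EVAL_SEEDS)


@pytest.fixture
def tiny_env():
    """A fast throwaway world for rule-level tests."""
    return pp.EnvConfig(N=10, nX=3, nY=10, max_steps=50)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
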