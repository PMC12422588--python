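"""Shared fixtures: the standard tasks and their (expensive) frontiers."""

import warnings

import pytest

import polcomp as pc


@pytest.fixture(scope="session")
def exp_task():
    return pc.make_experiment_task()


@pytest.fixture(scope="session")
def exp_frontier(exp_task):
    return pc.trace_frontier(exp_task)


@pytest.fixture(scope="session")
def rand_task():
    return pc.make_random_task(16, 32, rng_seed=1)


@pytest.fixture(scope="session")
def rand_frontier(rand_task):
    # a handful of near-tied betas stop at max_iter; the aggregated warning
    # is expected and the frontier invariants are validated on construction
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", pc.ConvergenceWarning)
        return pc.trace_frontier(rand_task)
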