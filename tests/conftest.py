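import itertools

import numpy as np
import pytest

from flymgwa import SimConfig, plant_effects, simulate_cfu, simulate_pangenome


def midranks(values):
    """Independent midrank computation (sorting-based, no scipy)."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def enumeration_rank_sum_p(x, y):
    """Brute-force two-sided rank-sum p over all C(N, n1) assignments.

    Oracle used across the suite: P(|W - E W| >= |w_obs - E W|) under
    random assignment of the pooled midranks to the first group.
    """
    pooled = list(x) + list(y)
    ranks = midranks(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n + 1) / 2.0
    w_obs = sum(ranks[:n1])
    dev = abs(w_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        w = sum(ranks[i] for i in comb)
        total += 1
        if abs(w - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated pipeline dataset shared across tests."""
    config = SimConfig(n_strains=16, n_ogs=200, seed=11)
    matrix, tree = simulate_pangenome(config)
    truth = plant_effects(matrix, config)
    records = simulate_cfu(truth, config)
    return config, matrix, tree, truth, records


@pytest.fixture
def rng():
    return np.random.default_rng(20230413)
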