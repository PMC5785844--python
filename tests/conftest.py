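import numpy as np
import pytest

from netdim import (
    DS_ES_32,
    ItemResponseMatrix,
    pearson_correlation,
    scenario_config,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def online_dataset():
    """One moderately large draw from the four-dimensional scenario."""
    return simulate_dataset(scenario_config("online_4dim", n=2000, seed=11))


@pytest.fixture(scope="session")
def online_corr(online_dataset):
    return pearson_correlation(online_dataset.responses)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(5)
    values = rng.integers(0, 5, size=(40, 32))
    return ItemResponseMatrix(values=values, scale=DS_ES_32)


def partitions_into_at_most(n, kmax):
    """All set partitions of range(n) with at most kmax blocks, as label arrays."""
    out = []

    def rec(i, labels, used):
        if i == n:
            out.append(np.array(labels))
            return
        for lab in range(min(used + 1, kmax)):
            labels.append(lab)
            rec(i + 1, labels, max(used, lab + 1))
            labels.pop()

    rec(0, [], 0)
    return out


def same_partition(a, b) -> bool:
    """True when two label vectors induce the same partition (up to relabeling)."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    return all((a[i] == a[j]) == (b[i] == b[j]) for i in range(n) for j in range(i + 1, n))


@pytest.fixture
def partition_helpers():
    return partitions_into_at_most, same_partition
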