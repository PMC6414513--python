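import heapq
import itertools

import numpy as np
import pandas as pd
import pytest

from cytosynth.io_core import ChannelDef, EventTable


def prufer_edges(prufer, n):
    """Decode a Prufer sequence into the labeled tree's edge list."""
    degree = [1] * n
    for v in prufer:
        degree[v] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for v in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, v))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    edges.append((heapq.heappop(leaves), heapq.heappop(leaves)))
    return edges


def brute_force_mst_length(points):
    """Minimum spanning-tree length by enumerating all n^(n-2) labeled trees."""
    from scipy.spatial.distance import cdist

    n = len(points)
    d = cdist(points, points)
    best = np.inf
    for prufer in itertools.product(range(n), repeat=n - 2):
        length = sum(d[a, b] for a, b in prufer_edges(prufer, n))
        best = min(best, length)
    return best


@pytest.fixture
def small_panel():
    return [
        ChannelDef("CD45", "Y89", "phenotype"),
        ChannelDef("CD19", "Nd144", "phenotype"),
        ChannelDef("IdU", "I127", "biosynthesis"),
        ChannelDef("BRU", "Sm150", "biosynthesis"),
        ChannelDef("Puromycin", "Gd158", "biosynthesis"),
    ]


@pytest.fixture
def small_table(small_panel):
    rng = np.random.default_rng(0)
    values = rng.poisson(50, size=(100, len(small_panel))).astype(float)
    labels = pd.DataFrame({"population": ["a"] * 50 + ["b"] * 50})
    return EventTable(values=values, channels=small_panel, labels=labels)


@pytest.fixture(scope="session")
def cellcycle_table():
    """One mid-sized cell-cycle acquisition shared across read-only tests."""
    from cytosynth import synthetic_data as sd

    design = sd.make_scenario("cellcycle", seed=42, n_events=20_000)
    return sd.simulate_experiment(design, seed=42)
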