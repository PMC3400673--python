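import numpy as np
import pytest

from barcodegap import (
    DistanceMatrix,
    distance_matrix,
    midpoint_root,
    neighbor_joining,
    scenario_paper_like,
)


def make_matrix(ids, dense):
    """DistanceMatrix from a dense array (sites filled with a safe constant)."""
    d = np.asarray(dense, dtype=float)
    sites = np.full_like(d, 1000, dtype=np.int64)
    np.fill_diagonal(sites, 0)
    return DistanceMatrix(ids=list(ids), d=d, sites=sites, flags={})


def random_additive_tree(rng, n):
    """Random binary tree topology with uniform branch lengths, as an
    adjacency list, plus its exact leaf-to-leaf path-length matrix computed
    by brute-force traversal (the oracle NJ must reproduce)."""
    nodes = list(range(n))
    adj = {i: [] for i in range(n)}
    nxt = n
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        adj[nxt] = []
        for child in (a, b):
            w = float(rng.uniform(0.05, 1.0))
            adj[nxt].append((child, w))
            adj[child].append((nxt, w))
        nodes = [x for x in nodes if x not in (a, b)] + [nxt]
        nxt += 1
    D = np.zeros((n, n))
    for leaf in range(n):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for other in range(n):
            D[leaf, other] = dist[other]
    return (D + D.T) / 2  # exact symmetry despite float summation order


@pytest.fixture(scope="session")
def scenario():
    """The full study-sized synthetic cohort with ground truth."""
    return scenario_paper_like(seed=1)


@pytest.fixture(scope="session")
def scenario_matrix(scenario):
    ds, _ = scenario
    return distance_matrix(ds)


@pytest.fixture(scope="session")
def scenario_tree(scenario_matrix):
    return midpoint_root(neighbor_joining(scenario_matrix))
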