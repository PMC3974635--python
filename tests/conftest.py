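"""Shared fixtures and small network builders for the test suite."""

import itertools

import numpy as np
import pytest

from wirecost import SpatialNetwork, cortical_like_fixture


def make_net(coords, edges, hemisphere=None, ids=None):
    """Build a SpatialNetwork from bare coordinates and an edge mapping.

    ``coords`` may be scalars (x positions, padded to 3-D) or 3-vectors;
    ``edges`` maps (i, j) index pairs to weights, or is an iterable of pairs
    (weight 1).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    if coords.shape[1] < 3:
        coords = np.hstack([coords, np.zeros((len(coords), 3 - coords.shape[1]))])
    if not isinstance(edges, dict):
        edges = {tuple(e): 1.0 for e in edges}
    else:
        edges = {tuple(k): v for k, v in edges.items()}
    node_ids = list(range(len(coords))) if ids is None else ids
    return SpatialNetwork(node_ids, coords, edges, hemisphere=hemisphere)


def random_weighted_net(n, n_edges, seed, binary=False):
    """A random weighted spatial graph: uniform 3-D coordinates, uniformly
    chosen edge set, log-normal weights."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 50, size=(n, 3))
    all_pairs = list(itertools.combinations(range(n), 2))
    idx = rng.choice(len(all_pairs), size=n_edges, replace=False)
    if binary:
        w = np.ones(n_edges)
    else:
        w = rng.lognormal(0, 1, size=n_edges)
    edges = {all_pairs[i]: float(wi) for i, wi in zip(idx, w)}
    return SpatialNetwork(list(range(n)), coords, edges)


@pytest.fixture
def path3():
    """3-node path a-b-c with unit weights at unit spacing."""
    return make_net([0.0, 1.0, 2.0], {(0, 1): 1.0, (1, 2): 1.0})


@pytest.fixture
def triangle():
    """Equal-weight triangle."""
    return make_net(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0]],
        {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0},
    )


@pytest.fixture
def square_cycle():
    """4-cycle on the unit square (side edges only)."""
    return make_net(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
        {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0, (0, 3): 1.0},
    )


@pytest.fixture
def star5():
    """Star K_{1,4}: hub node 0 linked to four leaves."""
    return make_net(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]],
        {(0, i): 1.0 for i in range(1, 5)},
    )


@pytest.fixture(scope="session")
def fixture_net():
    """The cortex-like 500-node test network (seed 0), shared per session."""
    return cortical_like_fixture(seed=0)
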