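"""Bottom-up minimally wired baseline networks (AM and DPM).

Given a node layout and a connection budget, the *absolute minimal* (AM)
network simply links the E spatially closest node pairs — the cheapest
possible E-edge wiring for that layout.  The *degree-preserving minimal*
(DPM) network walks the pair list from shortest to longest and adds a
connection only while both endpoints are still below their degree in the
source network, greedily approximating the source degree sequence at
near-minimal wiring cost.  Both baselines are unweighted (all weights 1) and
are compared with other networks by binary similarity only.

Distance ties are broken by the lexicographic (min-index, max-index) pair
order, so both constructions are deterministic.
"""

from __future__ import annotations

import numpy as np

from .network import SpatialNetwork

__all__ = ["absolute_minimal", "degree_preserving_minimal", "sorted_pairs"]


def sorted_pairs(net: SpatialNetwork) -> np.ndarray:
    """All node pairs (i < j) ordered by ascending Euclidean distance,
    ties broken lexicographically; shape (n*(n-1)/2, 2)."""
    n = net.n
    iu, ju = np.triu_indices(n, k=1)
    d = net.distance_matrix()[iu, ju]
    order = np.lexsort((ju, iu, d))
    return np.column_stack((iu[order], ju[order]))


def absolute_minimal(net: SpatialNetwork, n_edges: int | None = None) -> SpatialNetwork:
    """AM network: the ``n_edges`` spatially closest pairs (default: the
    source edge count), unweighted."""
    if net.n < 2 or net.n_edges < 1:
        raise ValueError("source network must have >= 2 nodes and >= 1 edge")
    E = net.n_edges if n_edges is None else n_edges
    max_edges = net.n * (net.n - 1) // 2
    if E > max_edges:
        raise ValueError(f"requested {E} edges but only {max_edges} pairs exist")
    chosen = sorted_pairs(net)[:E]
    edges = {(int(i), int(j)): 1.0 for i, j in chosen}
    return net.copy(edges=edges)


def degree_preserving_minimal(net: SpatialNetwork) -> SpatialNetwork:
    """DPM network: greedy shortest-first pass capped by source degrees.

    The result can have fewer edges than the source (some degree budget may
    be unfillable once short pairs are exhausted) and never exceeds any
    source degree.
    """
    if net.n < 2 or net.n_edges < 1:
        raise ValueError("source network must have >= 2 nodes and >= 1 edge")
    cap = net.degrees()
    deg = np.zeros_like(cap)
    edges: dict[tuple[int, int], float] = {}
    target = int(cap.sum()) // 2
    for i, j in sorted_pairs(net).tolist():
        if deg[i] < cap[i] and deg[j] < cap[j]:
            edges[(i, j)] = 1.0
            deg[i] += 1
            deg[j] += 1
            if len(edges) == target:
                break
    return net.copy(edges=edges)
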