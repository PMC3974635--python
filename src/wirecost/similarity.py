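"""Topological and spatial similarity between a network and its surrogates.

Topological overlap is measured by intersection-over-union similarity
quotients: binary (QS^b, on edge sets) and weighted (QS^w, on edge weights).
Spatial similarity is measured by the relative spatial displacement D: for
each region, its neighbours in the original network are greedily paired with
its neighbours in the surrogate by ascending distance, and each pair's
displacement is normalised by the length of the original connection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import SpatialNetwork

__all__ = [
    "PairingList",
    "similarity_binary",
    "similarity_weighted",
    "greedy_pairing",
    "spatial_displacement",
    "shared_connection_analysis",
]


@dataclass
class PairingList:
    """Greedy (original-neighbour, rewired-neighbour) pairing for one region."""

    pairs: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.pairs)


def _check_nodes(netA: SpatialNetwork, netB: SpatialNetwork) -> None:
    if netA.node_ids != netB.node_ids:
        raise ValueError("networks must be defined on the identical node set")


def similarity_binary(
    netA: SpatialNetwork, netB: SpatialNetwork, classical: bool = False
) -> float:
    """Binary similarity quotient QS^b between two networks on the same nodes.

    By default the intersection-over-union of the edge sets: 1 iff identical,
    0 iff disjoint.  ``classical=True`` gives the classical Sørensen form
    2|A∩B| / (|A| + |B|) instead.
    """
    _check_nodes(netA, netB)
    a, b = set(netA.edges), set(netB.edges)
    if not a and not b:
        return 1.0
    inter = len(a & b)
    if classical:
        return 2.0 * inter / (len(a) + len(b))
    return inter / len(a | b)


def similarity_weighted(
    netA: SpatialNetwork, netB: SpatialNetwork, classical: bool = False
) -> float:
    """Weighted similarity quotient QS^w between two networks on the same nodes.

    Shared overlap mass over union mass: for an edge present in both networks
    the numerator takes min(w_A, w_B) and the denominator max(w_A, w_B); an
    edge present in only one network contributes its full weight to the
    denominator.  Equals QS^b when all weights are equal; 1 iff the two
    weighted edge sets are identical.  ``classical=True`` normalises by the
    summed total weights, 2*Σmin / (W_A + W_B), instead.
    """
    _check_nodes(netA, netB)
    if not netA.edges and not netB.edges:
        return 1.0
    num = 0.0
    den = 0.0
    for e, wa in netA.edges.items():
        wb = netB.edges.get(e)
        if wb is None:
            den += wa
        else:
            num += min(wa, wb)
            den += max(wa, wb)
    for e, wb in netB.edges.items():
        if e not in netA.edges:
            den += wb
    if classical:
        total = sum(netA.edges.values()) + sum(netB.edges.values())
        return 2.0 * num / total
    return num / den


def greedy_pairing(
    original_neighbours, rewired_neighbours, coords: np.ndarray
) -> PairingList:
    """Greedily pair original with rewired neighbours by ascending distance.

    All cross distances are sorted ascending (ties resolved by the
    (original, rewired) lexicographic index order) and a pair is admitted iff
    neither member is already paired.  Empty inputs yield an empty pairing.
    """
    L = list(original_neighbours)
    M = list(rewired_neighbours)
    if not L or not M:
        return PairingList(pairs=[])
    C = np.asarray(coords, dtype=float)
    diff = C[L][:, None, :] - C[M][None, :, :]
    d = np.sqrt((diff * diff).sum(axis=2))
    li, mj = np.meshgrid(np.arange(len(L)), np.arange(len(M)), indexing="ij")
    order = np.lexsort(
        (np.array(M)[mj.ravel()], np.array(L)[li.ravel()], d.ravel())
    )
    used_l = [False] * len(L)
    used_m = [False] * len(M)
    pairs: list[tuple[int, int]] = []
    limit = min(len(L), len(M))
    for idx in order.tolist():
        i, j = idx // len(M), idx % len(M)
        if used_l[i] or used_m[j]:
            continue
        used_l[i] = True
        used_m[j] = True
        pairs.append((L[i], M[j]))
        if len(pairs) == limit:
            break
    return PairingList(pairs=pairs)


def spatial_displacement(
    source: SpatialNetwork, surrogate: SpatialNetwork, rewired_only: bool = False
) -> tuple[float, np.ndarray]:
    """Relative spatial displacement D between a network and a surrogate.

    For each region r, neighbours are paired greedily and each pair (l, m)
    contributes d(l, m) / d(r, l); the per-region displacement is the mean
    over its pairs, and the global D the mean over regions with at least one
    usable pair.  D = 0 iff the two networks are identical.  With
    ``rewired_only=True`` pairs with zero displacement (conserved
    connections) are excluded, measuring the displacement of the replaced
    connections only.  Pairs whose original neighbour coincides with r
    (zero-length original connection) are excluded with a warning.
    """
    _check_nodes(source, surrogate)
    D = source.distance_matrix()
    adj_src = source.adjacency_lists()
    adj_sur = surrogate.adjacency_lists()
    per_region = np.full(source.n, np.nan)
    warned = False
    for r in range(source.n):
        L, M = adj_src[r], adj_sur[r]
        if not L or not M:
            continue
        pairing = greedy_pairing(L, M, source.coords)
        vals = []
        for l, m in pairing.pairs:
            if rewired_only and l == m:
                continue
            ref = D[r, l]
            if ref == 0.0:
                if not warned:
                    warnings.warn(
                        "original neighbour at zero distance excluded from D"
                    )
                    warned = True
                continue
            vals.append(D[l, m] / ref)
        if vals:
            per_region[r] = float(np.mean(vals))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        global_D = float(np.nanmean(per_region))
    return global_D, per_region


def shared_connection_analysis(source: SpatialNetwork, ensemble) -> dict:
    """Connections collectively shared by all members of an ensemble.

    Reports the fraction of member edges present in every member, the
    fraction of those also present in the source network, and the mean
    pairwise intra-ensemble binary and weighted similarity quotients.
    """
    members = list(getattr(ensemble, "members", ensemble))
    if not members:
        raise ValueError("ensemble must be nonempty")
    shared = set(members[0].edges)
    for m in members[1:]:
        shared &= set(m.edges)
    n_edges = members[0].n_edges
    shared_fraction = len(shared) / n_edges if n_edges else 1.0
    in_source = (
        len(shared & set(source.edges)) / len(shared) if shared else float("nan")
    )
    qb, qw = [], []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            qb.append(similarity_binary(members[i], members[j]))
            qw.append(similarity_weighted(members[i], members[j]))
    return {
        "shared_fraction": shared_fraction,
        "shared_in_source_fraction": in_source,
        "n_shared": len(shared),
        "intra_qs_binary": float(np.mean(qb)) if qb else float("nan"),
        "intra_qs_weighted": float(np.mean(qw)) if qw else float("nan"),
    }
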