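"""Degree-preserving edge-swap surrogates under wiring-length constraints.

Three surrogate ensembles are produced by iterative constrained rewiring of a
source network.  A single rewiring step picks two connections (r1, r2) and
(r3, r4) at random and replaces them with (r1, r3) and (r2, r4), provided no
self-connection or parallel link would arise.  All three types preserve the
node set, the coordinates, the number of edges, the exact degree sequence and
the multiset of edge weights; they differ only in the spatial constraint
applied when accepting a swap:

``random``
    every valid swap is accepted — size / density / degree-sequence nulls;
``spatial``
    a swap is accepted only if, afterwards, the total Euclidean connection
    length of each of the four affected regions does not exceed that region's
    total in the *source* network — wiring-length-conserving nulls;
``reduced``
    only length-decreasing swaps are accepted (per affected region by
    default, or on the summed length of the swapped pair), driving wiring
    toward its minimum — wiring-length-optimised nulls.

Replacement edges inherit the weights of the removed ones: (r1, r3) takes
w(r1, r2) and (r2, r4) takes w(r3, r4), so only degree — not node strength —
is preserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import SpatialNetwork, _norm_edge

__all__ = [
    "RewiringConfig",
    "SurrogateEnsemble",
    "SwapCandidate",
    "required_swaps",
    "propose_swap",
    "accept_swap",
    "rewire",
    "generate_ensemble",
]

SURROGATE_TYPES = ("random", "spatial", "reduced")
DEFAULT_SWAPS_PER_EDGE = {"random": 20.0, "spatial": 20.0, "reduced": 1.0}


@dataclass
class RewiringConfig:
    """Parameters of the constrained rewiring process.

    ``swaps_per_edge`` defaults to 20 for random/spatial surrogates and to 1
    for reduced surrogates, whose acceptance rate saturates as fewer and fewer
    length-decreasing swaps remain.  ``max_attempts_factor`` bounds the total
    number of proposals at ``max_attempts_factor * required_swaps``.
    """

    surrogate_type: str = "random"
    swaps_per_edge: float | None = None
    max_attempts_factor: int = 1000
    reduced_mode: str = "per_region_strict"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.surrogate_type not in SURROGATE_TYPES:
            raise ValueError(f"unknown surrogate type {self.surrogate_type!r}")
        if self.reduced_mode not in ("per_region_strict", "total_length"):
            raise ValueError(f"unknown reduced mode {self.reduced_mode!r}")
        if self.swaps_per_edge is None:
            self.swaps_per_edge = DEFAULT_SWAPS_PER_EDGE[self.surrogate_type]
        if self.swaps_per_edge <= 0:
            raise ValueError("swaps_per_edge must be positive")
        if self.max_attempts_factor < 1:
            raise ValueError("max_attempts_factor must be >= 1")


@dataclass
class SwapCandidate:
    """A proposed swap: ``removed`` edges and their ``added`` replacements.

    ``added[0]`` inherits the weight of ``removed[0]`` and ``added[1]`` the
    weight of ``removed[1]``.
    """

    removed: tuple[tuple[int, int], tuple[int, int]]
    added: tuple[tuple[int, int], tuple[int, int]]


@dataclass
class SurrogateEnsemble:
    """A set of independently rewired surrogates plus generation provenance."""

    members: list[SpatialNetwork]
    config: RewiringConfig
    provenance: list[dict] = field(default_factory=list)


def required_swaps(n_edges: int, swaps_per_edge: float) -> int:
    """Number of accepted swaps so each edge is rewired ``swaps_per_edge``
    times on average: ``floor(swaps_per_edge * n_edges / 2)`` (each swap
    rewires two connections)."""
    if n_edges < 2:
        raise ValueError("need at least 2 edges to swap")
    return math.floor(swaps_per_edge * n_edges / 2)


def propose_swap(net: SpatialNetwork, rng: np.random.Generator) -> SwapCandidate | None:
    """Draw one swap proposal; ``None`` when it would create a self-connection
    or a parallel link (internal rejection, not an error)."""
    edges = list(net.edges)
    if len(edges) < 2:
        raise ValueError("need at least 2 edges to swap")
    e1, e2 = rng.integers(0, len(edges), size=2)
    if e1 == e2:
        return None
    r1, r2 = edges[e1]
    r3, r4 = edges[e2]
    if rng.integers(0, 2):
        r1, r2 = r2, r1
    if rng.integers(0, 2):
        r3, r4 = r4, r3
    new1, new2 = _norm_edge(r1, r3), _norm_edge(r2, r4)
    if r1 == r3 or r2 == r4 or new1 == new2:
        return None
    if new1 in net.edges or new2 in net.edges:
        return None
    return SwapCandidate(removed=(edges[e1], edges[e2]), added=(new1, new2))


def accept_swap(
    source_net: SpatialNetwork,
    current_net: SpatialNetwork,
    candidate: SwapCandidate,
    config: RewiringConfig,
) -> bool:
    """Spatial acceptance rule for a valid candidate (see module docstring)."""
    if config.surrogate_type == "random":
        return True
    D = source_net.distance_matrix()
    (a1, a2), (a3, a4) = candidate.removed
    (b1, b2), (b3, b4) = candidate.added
    if config.surrogate_type == "reduced" and config.reduced_mode == "total_length":
        return D[b1, b2] + D[b3, b4] < D[a1, a2] + D[a3, a4]
    delta = {}
    for (i, j), sign in (
        (candidate.removed[0], -1.0),
        (candidate.removed[1], -1.0),
        (candidate.added[0], +1.0),
        (candidate.added[1], +1.0),
    ):
        d = sign * D[i, j]
        delta[i] = delta.get(i, 0.0) + d
        delta[j] = delta.get(j, 0.0) + d
    L = current_net.region_lengths()
    if config.surrogate_type == "spatial":
        L0 = source_net.region_lengths()
        return all(L[r] + dr <= L0[r] + 1e-9 for r, dr in delta.items())
    # reduced, per_region_strict: every affected region strictly decreases
    return all(dr < 0.0 for r, dr in delta.items())


def _swap_batch_python(
    pairs, adj, dist, L, L0, ee, oo, mode, strict, accepted, required,
    trace, trace_n, record_trace, total_len,
):
    """Pure-Python batch of swap proposals; mirrors the compiled kernel."""
    m = ee.shape[0]
    used = 0
    for idx in range(m):
        used += 1
        e1, e2 = ee[idx, 0], ee[idx, 1]
        if e1 == e2:
            continue
        r1, r2 = pairs[e1, 0], pairs[e1, 1]
        r3, r4 = pairs[e2, 0], pairs[e2, 1]
        if oo[idx, 0]:
            r1, r2 = r2, r1
        if oo[idx, 1]:
            r3, r4 = r4, r3
        if r1 == r3 or r2 == r4:
            continue
        if adj[r1, r3] or adj[r2, r4]:
            continue
        d12 = dist[r1, r2]
        d34 = dist[r3, r4]
        d13 = dist[r1, r3]
        d24 = dist[r2, r4]
        if mode == 1:
            if (
                L[r1] - d12 + d13 > L0[r1]
                or L[r2] - d12 + d24 > L0[r2]
                or L[r3] - d34 + d13 > L0[r3]
                or L[r4] - d34 + d24 > L0[r4]
            ):
                continue
        elif mode == 2:
            if strict:
                if not (d13 < d12 and d24 < d12 and d13 < d34 and d24 < d34):
                    continue
            else:
                if not d13 + d24 < d12 + d34:
                    continue
        # accept: relocate the two connections (weights ride along)
        adj[r1, r2] = adj[r2, r1] = 0
        adj[r3, r4] = adj[r4, r3] = 0
        adj[r1, r3] = adj[r3, r1] = 1
        adj[r2, r4] = adj[r4, r2] = 1
        if r1 < r3:
            pairs[e1, 0], pairs[e1, 1] = r1, r3
        else:
            pairs[e1, 0], pairs[e1, 1] = r3, r1
        if r2 < r4:
            pairs[e2, 0], pairs[e2, 1] = r2, r4
        else:
            pairs[e2, 0], pairs[e2, 1] = r4, r2
        L[r1] += d13 - d12
        L[r2] += d24 - d12
        L[r3] += d13 - d34
        L[r4] += d24 - d34
        accepted += 1
        if record_trace:
            total_len += d13 + d24 - d12 - d34
            trace[trace_n] = total_len
            trace_n += 1
        if accepted >= required:
            break
    return accepted, used, trace_n, total_len


try:  # compiled batch kernel: the proposal loop is the hot path
    from numba import njit

    _swap_batch = njit(cache=True)(_swap_batch_python)
except ImportError:  # pragma: no cover - numba is a declared dependency
    _swap_batch = _swap_batch_python

_MODE = {"random": 0, "spatial": 1, "reduced": 2}


def _rewire_fast(
    net: SpatialNetwork,
    config: RewiringConfig,
    seed: int,
    record_length_trace: bool,
) -> tuple[dict[tuple[int, int], float], dict]:
    """Array-based rewiring loop; returns (edge dict, provenance)."""
    rng = np.random.default_rng(seed)
    n = net.n
    weights = list(net.edges.values())
    pairs = np.array(list(net.edges.keys()), dtype=np.int64)
    E = len(pairs)
    required = required_swaps(E, config.swaps_per_edge)
    max_attempts = config.max_attempts_factor * required

    adj = np.zeros((n, n), dtype=np.uint8)
    adj[pairs[:, 0], pairs[:, 1]] = 1
    adj[pairs[:, 1], pairs[:, 0]] = 1
    dist = net.distance_matrix()
    L0 = net.region_lengths()
    L = L0.copy()
    mode = _MODE[config.surrogate_type]
    strict = config.reduced_mode == "per_region_strict"

    trace = np.empty(required if record_length_trace else 0)
    trace_n = 0
    total_len = float(L.sum()) / 2.0

    accepted = 0
    attempted = 0
    batch = 1 << 20
    while accepted < required and attempted < max_attempts:
        m = min(batch, max_attempts - attempted)
        ee = rng.integers(0, E, size=(m, 2))
        oo = rng.integers(0, 2, size=(m, 2)).astype(np.uint8)
        accepted, used, trace_n, total_len = _swap_batch(
            pairs, adj, dist, L, L0, ee, oo, mode, strict, accepted,
            required, trace, trace_n, record_length_trace, total_len,
        )
        attempted += used

    provenance = {
        "seed": seed,
        "surrogate_type": config.surrogate_type,
        "required_swaps": required,
        "accepted_swaps": accepted,
        "attempted_swaps": attempted,
        "saturated": accepted < required,
    }
    if record_length_trace:
        provenance["length_trace"] = trace[:trace_n].tolist()
    edges = {
        (int(i), int(j)): w for (i, j), w in zip(pairs.tolist(), weights)
    }
    return edges, provenance


def rewire(
    net: SpatialNetwork,
    config: RewiringConfig,
    seed: int | None = None,
    record_length_trace: bool = False,
) -> tuple[SpatialNetwork, dict]:
    """Produce one surrogate network and its generation provenance.

    The process repeats propose/accept until ``required_swaps`` swaps are
    accepted or the attempt budget is exhausted (reduced surrogates may
    saturate as length-decreasing swaps run out; saturation is recorded in
    the provenance, never fatal).
    """
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    if seed is None:
        seed = config.seed
    edges, provenance = _rewire_fast(net, config, seed, record_length_trace)
    return net.copy(edges=edges), provenance


def generate_ensemble(
    net: SpatialNetwork, config: RewiringConfig, n_members: int
) -> SurrogateEnsemble:
    """Generate ``n_members`` independent surrogates (member i uses seed
    ``config.seed + i``, so results do not depend on execution order)."""
    members, prov = [], []
    for i in range(n_members):
        member, p = rewire(net, config, seed=config.seed + i)
        members.append(member)
        prov.append(p)
    return SurrogateEnsemble(members=members, config=config, provenance=prov)
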