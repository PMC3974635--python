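"""Newman spectral module detection and partition-consistency analysis.

Module detection recursively bipartitions the network by the sign of the
leading eigenvector of the (generalised, for subgraphs) weighted modularity
matrix B_ij = w_ij - k_i^w k_j^w / (2W); a split is kept only while it
increases the global modularity index Q.  Partition consistency across an
ensemble is measured per node by scaled inclusivity, the squared-intersection
overlap between the node's module in a reference partition and its module in
each ensemble partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SpatialNetwork

__all__ = [
    "ModulePartition",
    "modularity_Q",
    "spectral_partition",
    "scaled_inclusivity",
    "module_correspondence",
    "module_connection_stats",
]


@dataclass
class ModulePartition:
    """Disjoint node -> module assignment with its modularity score.

    ``labels`` holds one integer module id per node (in node order); ids are
    consecutive from 0 in order of first appearance.
    """

    labels: np.ndarray
    Q: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))

    @property
    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)

    def modules(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.labels == m) for m in np.unique(self.labels)]


def _as_labels(net: SpatialNetwork, assignment) -> np.ndarray:
    """Accept a label array, a ModulePartition, or a node_id -> module dict."""
    if isinstance(assignment, ModulePartition):
        return assignment.labels
    if isinstance(assignment, dict):
        missing = [nid for nid in net.node_ids if nid not in assignment]
        if missing:
            raise ValueError(f"partition does not cover nodes: {missing[:5]}")
        raw = [assignment[nid] for nid in net.node_ids]
    else:
        raw = list(assignment)
        if len(raw) != net.n:
            raise ValueError("partition does not cover all nodes")
    order: dict = {}
    for m in raw:
        if m not in order:
            order[m] = len(order)
    return np.array([order[m] for m in raw], dtype=int)


def modularity_Q(net: SpatialNetwork, assignment) -> float:
    """Weighted Newman modularity of a partition.

    Q = (1/2W) * sum_ij [w_ij - k_i^w k_j^w / (2W)] delta(m_i, m_j), with W
    the total edge weight and k^w the node strengths.  Q = 0 for the trivial
    single-module partition.
    """
    labels = _as_labels(net, assignment)
    W = sum(net.edges.values())
    if W == 0:
        return 0.0
    strengths = net.strengths()
    nmod = labels.max() + 1
    within = np.zeros(nmod)
    for (i, j), w in net.edges.items():
        if labels[i] == labels[j]:
            within[labels[i]] += w
    a = np.bincount(labels, weights=strengths, minlength=nmod) / (2.0 * W)
    return float(np.sum(within / W - a**2))


def _components(net: SpatialNetwork) -> list[np.ndarray]:
    n = net.n
    adj = net.adjacency_lists()
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in adj[i]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(np.array(sorted(comp)))
    return comps


def _leading_split(B_g: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Sign split from the leading eigenvector of a generalised modularity
    matrix; None when the leading eigenvalue is non-positive.  Zero entries
    go to the positive block; overall sign fixed deterministically."""
    vals, vecs = np.linalg.eigh(B_g)
    lead = np.argmax(vals)
    if vals[lead] <= 1e-12:
        return None
    v = vecs[:, lead]
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if len(nz) and v[nz[0]] < 0:
        v = -v
    s = np.where(v >= 0, 1.0, -1.0)
    return s, float(vals[lead])


def _fine_tune(B_g: np.ndarray, s: np.ndarray) -> np.ndarray:
    """One Kernighan-Lin style sweep: greedily move single nodes across the
    bipartition while the modularity gain is positive."""
    s = s.copy()
    improved = True
    while improved:
        improved = False
        gains = -4.0 * s * (B_g @ s) + 4.0 * np.diag(B_g)
        best = int(np.argmax(gains))
        if gains[best] > 1e-12:
            s[best] = -s[best]
            improved = True
    return s


def spectral_partition(
    net: SpatialNetwork, fine_tune: bool = False
) -> ModulePartition:
    """Recursive leading-eigenvector module detection.

    Connected components are handled independently; each group is split by
    the sign of the leading eigenvector of its generalised modularity matrix
    and the recursion stops when no split increases the global Q.
    Deterministic: eigenvectors come from a full symmetric eigendecomposition
    with a fixed sign convention, and zero entries join the positive block.
    """
    n = net.n
    W = sum(net.edges.values())
    labels = np.zeros(n, dtype=int)
    if n == 0 or W == 0:
        return ModulePartition(labels=labels, Q=0.0)
    Wmat = net.weight_matrix()
    k = net.strengths()
    B = Wmat - np.outer(k, k) / (2.0 * W)

    groups = _components(net)
    final: list[np.ndarray] = []
    while groups:
        g = groups.pop()
        if len(g) < 2:
            final.append(g)
            continue
        B_g = B[np.ix_(g, g)]
        B_g = B_g - np.diag(B_g.sum(axis=1))
        split = _leading_split(B_g)
        if split is None:
            final.append(g)
            continue
        s, _ = split
        if fine_tune:
            s = _fine_tune(B_g, s)
        dQ = float(s @ B_g @ s) / (4.0 * W)
        left, right = g[s > 0], g[s < 0]
        if dQ <= 1e-12 or len(left) == 0 or len(right) == 0:
            final.append(g)
            continue
        groups.append(left)
        groups.append(right)
    for m, g in enumerate(sorted(final, key=lambda a: int(a[0]))):
        labels[g] = m
    return ModulePartition(labels=labels, Q=modularity_Q(net, labels))


def scaled_inclusivity(
    reference: ModulePartition, ensemble_partitions
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node scaled inclusivity of a reference partition in an ensemble.

    For member partition P and reference R, the module-by-module similarity
    is X(p, q) = |P_p ∩ R_q|^2 / (|P_p| * |R_q|) in [0, 1]; each node scores
    the X of the pair of modules containing it, and its SI is the mean over
    ensemble members.  Returns (mean, standard deviation) per node; SI = 1
    everywhere iff every member partitions the nodes exactly like the
    reference.
    """
    members = list(ensemble_partitions)
    if not members:
        raise ValueError("ensemble of partitions must be nonempty")
    ref = reference.labels
    n = len(ref)
    ref_sizes = np.bincount(ref)
    scores = np.empty((len(members), n))
    for mi, part in enumerate(members):
        lab = part.labels if isinstance(part, ModulePartition) else np.asarray(part)
        if len(lab) != n:
            raise ValueError("all partitions must cover the same node set")
        p_sizes = np.bincount(lab)
        inter = np.zeros((lab.max() + 1, ref.max() + 1))
        np.add.at(inter, (lab, ref), 1.0)
        X = inter**2 / np.outer(p_sizes, ref_sizes)
        scores[mi] = X[lab, ref]
    return scores.mean(axis=0), scores.std(axis=0)


def module_correspondence(ensemble_partitions) -> np.ndarray:
    """Node-by-node co-assignment frequency matrix over an ensemble of
    partitions: entry (i, j) is the fraction of partitions placing i and j
    in the same module (symmetric, unit diagonal)."""
    members = list(ensemble_partitions)
    if not members:
        raise ValueError("need at least one partition")
    lab0 = members[0].labels if isinstance(members[0], ModulePartition) else members[0]
    n = len(lab0)
    freq = np.zeros((n, n))
    for part in members:
        lab = part.labels if isinstance(part, ModulePartition) else np.asarray(part)
        freq += lab[:, None] == lab[None, :]
    return freq / len(members)


def module_connection_stats(net: SpatialNetwork, assignment) -> dict:
    """Intra/inter-module connection counts and densities for a partition."""
    labels = _as_labels(net, assignment)
    sizes = np.bincount(labels)
    intra_pairs = int((sizes * (sizes - 1) // 2).sum())
    total_pairs = net.n * (net.n - 1) // 2
    inter_pairs = total_pairs - intra_pairs
    intra_edges = sum(1 for (i, j) in net.edges if labels[i] == labels[j])
    inter_edges = net.n_edges - intra_edges
    return {
        "intra_edge_fraction": intra_edges / net.n_edges if net.n_edges else float("nan"),
        "intra_edges": intra_edges,
        "inter_edges": inter_edges,
        "intra_density": intra_edges / intra_pairs if intra_pairs else float("nan"),
        "inter_density": inter_edges / inter_pairs if inter_pairs else float("nan"),
        "global_density": net.n_edges / total_pairs if total_pairs else float("nan"),
    }
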