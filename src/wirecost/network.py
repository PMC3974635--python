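"""Spatially embedded weighted networks: data model, I/O, aggregation.

The central object is :class:`SpatialNetwork`, an undirected simple graph whose
nodes carry 3-D positions (in mm) and optional hemisphere / anatomical-structure
labels, and whose edges carry positive real weights.  Connection lengths are
always the Euclidean distances between endpoint coordinates, recomputed on
demand and never stored as authoritative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpatialNetwork",
    "RegionGrouping",
    "read_network",
    "read_matrix",
    "write_network",
    "aggregate_to_groups",
    "extract_subnetwork",
    "density",
]


class NetworkError(ValueError):
    """Raised on invalid network construction or I/O input."""


def _norm_edge(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass
class SpatialNetwork:
    """Undirected, simple, weighted graph embedded in 3-D space.

    Parameters
    ----------
    node_ids
        Ordered node identifiers (strings or ints; kept as given).
    coords
        Array of shape ``(n, 3)`` with node positions in mm.
    edges
        Mapping ``(i, j) -> weight`` over *integer node indices* with
        ``i < j`` and ``weight > 0``.
    hemisphere, structure
        Optional per-node label sequences.
    """

    node_ids: list
    coords: np.ndarray
    edges: dict[tuple[int, int], float]
    hemisphere: list | None = None
    structure: list | None = None
    _index: dict = field(default=None, repr=False, compare=False)
    _dist: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.node_ids), 3):
            raise NetworkError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.node_ids)} nodes"
            )
        if not np.all(np.isfinite(self.coords)):
            raise NetworkError("coordinates must be finite")
        if len(set(map(str, self.node_ids))) != len(self.node_ids):
            raise NetworkError("duplicate node ids")
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}
        n = self.n
        clean: dict[tuple[int, int], float] = {}
        for (i, j), w in self.edges.items():
            if i == j:
                raise NetworkError(f"self-loop on node {self.node_ids[i]}")
            if not (0 <= i < n and 0 <= j < n):
                raise NetworkError(f"edge ({i}, {j}) references unknown node index")
            w = float(w)
            if not np.isfinite(w) or w <= 0:
                raise NetworkError(f"non-positive weight {w} on edge ({i}, {j})")
            key = _norm_edge(i, j)
            if key in clean and clean[key] != w:
                raise NetworkError(f"conflicting duplicate weights for edge {key}")
            clean[key] = w
        self.edges = clean
        if self.hemisphere is not None:
            self.hemisphere = list(self.hemisphere)
            if len(self.hemisphere) != n:
                raise NetworkError("hemisphere labels do not match node count")
        if self.structure is not None:
            self.structure = list(self.structure)
            if len(self.structure) != n:
                raise NetworkError("structure labels do not match node count")

    # ------------------------------------------------------------------ basics
    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node_id) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise NetworkError(f"unknown node id {node_id!r}") from None

    def copy(self, edges: dict | None = None) -> "SpatialNetwork":
        """Copy, optionally replacing the edge set (coords are shared)."""
        net = SpatialNetwork.__new__(SpatialNetwork)
        net.node_ids = self.node_ids
        net.coords = self.coords
        net.hemisphere = self.hemisphere
        net.structure = self.structure
        net._index = self._index
        net._dist = self._dist
        net.edges = dict(self.edges) if edges is None else edges
        return net

    # ------------------------------------------------------------- derived
    def degrees(self) -> np.ndarray:
        k = np.zeros(self.n, dtype=int)
        for i, j in self.edges:
            k[i] += 1
            k[j] += 1
        return k

    def strengths(self) -> np.ndarray:
        s = np.zeros(self.n)
        for (i, j), w in self.edges.items():
            s[i] += w
            s[j] += w
        return s

    def weight_matrix(self) -> np.ndarray:
        """Dense symmetric weight matrix with zero diagonal."""
        W = np.zeros((self.n, self.n))
        for (i, j), w in self.edges.items():
            W[i, j] = W[j, i] = w
        return W

    def distance_matrix(self) -> np.ndarray:
        """Euclidean inter-node distance matrix (cached)."""
        if self._dist is None or self._dist.shape[0] != self.n:
            d = self.coords[:, None, :] - self.coords[None, :, :]
            self._dist = np.sqrt((d * d).sum(axis=2))
        return self._dist

    def edge_array(self) -> np.ndarray:
        """Edges as an ``(E, 2)`` int array (i < j), in insertion order."""
        if not self.edges:
            return np.empty((0, 2), dtype=int)
        return np.array(list(self.edges), dtype=int)

    def edge_lengths(self) -> np.ndarray:
        e = self.edge_array()
        if len(e) == 0:
            return np.empty(0)
        return self.distance_matrix()[e[:, 0], e[:, 1]]

    def total_length(self) -> float:
        return float(self.edge_lengths().sum())

    def region_lengths(self) -> np.ndarray:
        """Per-node total Euclidean length of incident connections."""
        out = np.zeros(self.n)
        D = self.distance_matrix()
        for i, j in self.edges:
            d = D[i, j]
            out[i] += d
            out[j] += d
        return out

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def adjacency_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for (i, j), w in self.edges.items():
            g.add_edge(i, j, weight=w)
        return g

    def binarized(self) -> "SpatialNetwork":
        """Same edge set with all weights set to 1."""
        return self.copy(edges={e: 1.0 for e in self.edges})


@dataclass
class RegionGrouping:
    """Total mapping from node id to group id (high -> low resolution)."""

    mapping: Mapping

    def group_ids(self) -> list:
        seen: dict = {}
        for g in self.mapping.values():
            if g not in seen:
                seen[g] = None
        return list(seen)


# ---------------------------------------------------------------------- I/O

def read_network(node_table_path, edge_table_path) -> SpatialNetwork:
    """Read a network from node and edge TSV tables.

    The node table must have columns ``id, x, y, z`` and may have
    ``hemisphere`` and ``structure``.  The edge table must have columns
    ``source, target, weight``.  Duplicate (symmetric) edge rows collapse only
    when their weights agree; conflicting duplicates are an error.
    """
    nodes = pd.read_csv(node_table_path, sep="\t", dtype={"id": str})
    for col in ("id", "x", "y", "z"):
        if col not in nodes.columns:
            raise NetworkError(f"node table missing column {col!r}")
    ids = nodes["id"].tolist()
    coords = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    hemi = nodes["hemisphere"].tolist() if "hemisphere" in nodes.columns else None
    struct = nodes["structure"].tolist() if "structure" in nodes.columns else None
    index = {nid: i for i, nid in enumerate(ids)}

    etab = pd.read_csv(edge_table_path, sep="\t", dtype={"source": str, "target": str})
    for col in ("source", "target", "weight"):
        if col not in etab.columns:
            raise NetworkError(f"edge table missing column {col!r}")
    edges: dict[tuple[int, int], float] = {}
    for src, tgt, w in etab.itertuples(index=False):
        if src not in index:
            raise NetworkError(f"edge endpoint {src!r} not in node table")
        if tgt not in index:
            raise NetworkError(f"edge endpoint {tgt!r} not in node table")
        if src == tgt:
            raise NetworkError(f"self-loop row on node {src!r}")
        try:
            w = float(w)
        except (TypeError, ValueError):
            raise NetworkError(f"non-numeric weight {w!r}") from None
        if not np.isfinite(w) or w <= 0:
            raise NetworkError(f"non-positive weight {w} on edge ({src}, {tgt})")
        key = _norm_edge(index[src], index[tgt])
        if key in edges and edges[key] != w:
            raise NetworkError(
                f"conflicting duplicate weights for edge ({src}, {tgt}): "
                f"{edges[key]} vs {w}"
            )
        edges[key] = w
    return SpatialNetwork(ids, coords, edges, hemisphere=hemi, structure=struct)


def write_network(net: SpatialNetwork, node_table_path, edge_table_path) -> None:
    """Write node and edge TSV tables (inverse of :func:`read_network`)."""
    cols = {"id": [str(i) for i in net.node_ids]}
    cols["x"], cols["y"], cols["z"] = net.coords.T
    if net.hemisphere is not None:
        cols["hemisphere"] = net.hemisphere
    if net.structure is not None:
        cols["structure"] = net.structure
    pd.DataFrame(cols).to_csv(node_table_path, sep="\t", index=False)
    rows = [
        (str(net.node_ids[i]), str(net.node_ids[j]), repr(w))
        for (i, j), w in sorted(net.edges.items())
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        edge_table_path, sep="\t", index=False
    )


def read_matrix(
    matrix_path, node_table_path, delimiter: str | None = None
) -> SpatialNetwork:
    """Read a dense symmetric connectivity matrix plus a node coordinate table.

    Row/column order follows the node-table order.  The matrix must be square,
    symmetric (to 1e-9) and zero on the diagonal; nonzero entries become edges.
    """
    nodes = pd.read_csv(node_table_path, sep="\t", dtype={"id": str})
    ids = nodes["id"].tolist()
    coords = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    hemi = nodes["hemisphere"].tolist() if "hemisphere" in nodes.columns else None
    struct = nodes["structure"].tolist() if "structure" in nodes.columns else None

    M = np.loadtxt(matrix_path, delimiter=delimiter, ndmin=2)
    if M.shape[0] != M.shape[1]:
        raise NetworkError(f"matrix is not square: {M.shape}")
    if M.shape[0] != len(ids):
        raise NetworkError(
            f"matrix size {M.shape[0]} does not match {len(ids)} nodes"
        )
    if np.max(np.abs(M - M.T)) > 1e-9:
        raise NetworkError("matrix is asymmetric beyond tolerance 1e-9")
    if np.any(np.abs(np.diag(M)) > 0):
        raise NetworkError("matrix has nonzero diagonal entries")
    ii, jj = np.nonzero(np.triu(M, k=1))
    edges = {(int(i), int(j)): float(M[i, j]) for i, j in zip(ii, jj)}
    if not edges:
        warnings.warn("connectivity matrix contains no nonzero entries")
    return SpatialNetwork(ids, coords, edges, hemisphere=hemi, structure=struct)


# ------------------------------------------------------------- operations

def aggregate_to_groups(
    net: SpatialNetwork, grouping: RegionGrouping
) -> SpatialNetwork:
    """Aggregate a high-resolution network onto groups of nodes.

    Each group becomes one node positioned at the unweighted centroid of its
    members; the weight of an inter-group edge is the sum of the weights of
    all member-pair edges crossing the two groups.  Intra-group edges are
    discarded, so total weight is conserved minus the intra-group weight.
    """
    missing = [nid for nid in net.node_ids if nid not in grouping.mapping]
    if missing:
        raise NetworkError(f"grouping missing nodes: {missing[:5]}")
    gids = []
    seen = set()
    for nid in net.node_ids:
        g = grouping.mapping[nid]
        if g not in seen:
            seen.add(g)
            gids.append(g)
    gindex = {g: i for i, g in enumerate(gids)}
    node_group = np.array([gindex[grouping.mapping[nid]] for nid in net.node_ids])

    coords = np.zeros((len(gids), 3))
    for gi in range(len(gids)):
        coords[gi] = net.coords[node_group == gi].mean(axis=0)

    edges: dict[tuple[int, int], float] = {}
    for (i, j), w in net.edges.items():
        gi, gj = node_group[i], node_group[j]
        if gi == gj:
            continue
        key = _norm_edge(int(gi), int(gj))
        edges[key] = edges.get(key, 0.0) + w
    return SpatialNetwork(gids, coords, edges)


def extract_subnetwork(net: SpatialNetwork, node_subset: Iterable) -> SpatialNetwork:
    """Induced subgraph on a subset of node ids; labels/coords retained."""
    subset = list(node_subset)
    idx = [net.index_of(nid) for nid in subset]
    remap = {old: new for new, old in enumerate(idx)}
    keep = set(idx)
    edges = {
        _norm_edge(remap[i], remap[j]): w
        for (i, j), w in net.edges.items()
        if i in keep and j in keep
    }
    hemi = [net.hemisphere[i] for i in idx] if net.hemisphere is not None else None
    struct = [net.structure[i] for i in idx] if net.structure is not None else None
    return SpatialNetwork(
        subset, net.coords[idx], edges, hemisphere=hemi, structure=struct
    )


def density(net: SpatialNetwork) -> float:
    """Connection density E / (n(n-1)/2), as a fraction in [0, 1]."""
    if net.n < 2:
        raise NetworkError("density undefined for fewer than 2 nodes")
    return net.n_edges / (net.n * (net.n - 1) / 2)
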