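"""Correlation-weighted residue networks and allosteric coupling paths.

A residue network places one node at each C-alpha. An edge joins two
residues whose minimal heavy-atom distance stays within a cutoff (default
4.5 A) for at least a persistence fraction (default 0.75) of the sampled
frames, and carries weight

    w_ij = -log |C_ij|,

where C_ij is the normalized cross-correlation of the C-alpha fluctuation
vectors. Short network paths (small summed weight) then trace strongly
coupled, persistently packed routes -- the standard dynamic-network picture
of allosteric communication. Optimal and suboptimal (k-shortest loopless)
paths between a sensor residue and a pore residue identify candidate
coupling pathways such as the BK channel C-linker.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .traj import Selection, Trajectory

__all__ = [
    "CorrelationMatrix",
    "ContactGraph",
    "CouplingPath",
    "NoPathError",
    "correlation_matrix",
    "build_contact_graph",
    "optimal_path",
    "suboptimal_paths",
    "path_domain_fraction",
    "all_pairs_distances",
]

NodeId = tuple[str, int]


class NoPathError(ValueError):
    """Source and target live in different connected components."""


@dataclass
class CorrelationMatrix:
    """Normalized residue-residue fluctuation correlations at the C-alpha."""

    node_ids: list[NodeId]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.node_ids)
        if self.C.shape != (n, n):
            raise ValueError(f"C must be {n}x{n}")
        if not np.allclose(self.C, self.C.T, atol=1e-9):
            raise ValueError("C must be symmetric")
        if not np.allclose(np.diag(self.C), 1.0, atol=1e-9):
            raise ValueError("C must have unit diagonal")
        if np.any(np.abs(self.C) > 1 + 1e-9):
            raise ValueError("|C_ij| must not exceed 1")

    def value(self, a: NodeId, b: NodeId) -> float:
        i = self.node_ids.index(a)
        j = self.node_ids.index(b)
        return float(self.C[i, j])


@dataclass
class ContactGraph:
    """Persistence-filtered residue graph with w_ij = -log|C_ij| edge weights."""

    graph: nx.Graph
    distance_cutoff: float = 4.5
    persistence_threshold: float = 0.75
    log_base: float = math.e

    @property
    def nodes(self) -> list[NodeId]:
        return sorted(self.graph.nodes)

    def to_edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b, d in sorted(self.graph.edges(data=True)):
            rows.append({"chain_a": a[0], "resid_a": a[1], "chain_b": b[0],
                         "resid_b": b[1], "persistence": d["persistence"],
                         "C_ij": d["C"], "w_ij": d["weight"]})
        return pd.DataFrame(rows)

    def write_edge_csv(self, path: str) -> None:
        self.to_edge_table().to_csv(path, index=False)

    def write_graphml(self, path: str) -> None:
        g = nx.Graph()
        for node in self.graph.nodes:
            g.add_node(f"{node[0]}:{node[1]}")
        for a, b, d in self.graph.edges(data=True):
            g.add_edge(f"{a[0]}:{a[1]}", f"{b[0]}:{b[1]}", **d)
        nx.write_graphml(g, path)


@dataclass
class CouplingPath:
    """A simple source->target path; rank 1 is the optimal path."""

    nodes: list[NodeId]
    total_length: float
    rank: int = 1

    def __len__(self) -> int:
        return len(self.nodes)

    def to_dict(self) -> dict:
        return {"rank": self.rank, "total_length": self.total_length,
                "residues": [[c, int(r)] for c, r in self.nodes]}


def correlation_matrix(traj: Trajectory, sel: Selection | None = None,
                       stride: int = 1) -> CorrelationMatrix:
    """Normalized covariance of 3-D C-alpha fluctuation vectors.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr_i(t) the
    displacement of node i from its trajectory mean; the trajectory must be
    superposed beforehand so internal motion is not swamped by rigid drift.
    """
    from .traj import CA_PROTEIN
    sel = sel if sel is not None else CA_PROTEIN
    idx = sel.indices(traj.topology)
    top = traj.topology
    seen: dict[NodeId, int] = {}
    for i in idx:
        key = (top.chain_id[i], int(top.residue_id[i]))
        if key in seen:
            raise ValueError(f"selection yields more than one atom for residue {key}")
        seen[key] = i
    node_ids = list(seen)
    frames = np.arange(0, traj.n_frames, max(1, int(stride)))
    if len(frames) < 2:
        raise ValueError("need at least 2 sampled frames")
    X = traj.coords[np.ix_(frames, list(seen.values()))]  # (T, N, 3)
    X = X - X.mean(axis=0, keepdims=True)
    A = np.transpose(X, (1, 0, 2)).reshape(len(node_ids), -1)  # N x (T*3)
    num = A @ A.T
    var = np.diag(num).copy()
    zero = np.flatnonzero(var <= 0)
    if len(zero):
        raise ValueError(
            f"zero-variance node(s) {[node_ids[i] for i in zero]}: "
            "correlation normalization is undefined")
    C = num / np.sqrt(np.outer(var, var))
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(node_ids, C)


def contact_persistence(traj: Trajectory, node_ids: list[NodeId],
                        cutoff: float = 4.5, stride: int = 1,
                        frames: np.ndarray | None = None) -> dict[tuple[NodeId, NodeId], float]:
    """Fraction of sampled frames in which each residue pair's minimal
    heavy-atom distance is <= cutoff. Pairs never in contact are omitted."""
    top = traj.topology
    heavy = np.flatnonzero(top.heavy_mask)
    atom_node = {}
    node_index = {n: k for k, n in enumerate(node_ids)}
    for i in heavy:
        key = (top.chain_id[i], int(top.residue_id[i]))
        if key in node_index:
            atom_node[i] = node_index[key]
    atoms = np.asarray(sorted(atom_node))
    owner = np.asarray([atom_node[i] for i in atoms])
    if frames is None:
        frames = np.arange(0, traj.n_frames, max(1, int(stride)))
    counts: dict[tuple[int, int], int] = {}
    for f in frames:
        tree = cKDTree(traj.coords[f][atoms])
        seen_pairs: set[tuple[int, int]] = set()
        for ai, aj in tree.query_pairs(cutoff):
            ni, nj = owner[ai], owner[aj]
            if ni == nj:
                continue
            pair = (min(ni, nj), max(ni, nj))
            seen_pairs.add(pair)
        for pair in seen_pairs:
            counts[pair] = counts.get(pair, 0) + 1
    nT = len(frames)
    return {(node_ids[i], node_ids[j]): c / nT for (i, j), c in counts.items()}


def build_contact_graph(traj: Trajectory, corr: CorrelationMatrix,
                        cutoff: float = 4.5, persistence: float = 0.75,
                        stride: int = 1, frames: np.ndarray | None = None,
                        exclude_sequence_neighbors: bool = False) -> ContactGraph:
    """Residue graph: edges are contacts persisting >= ``persistence`` of
    frames, weighted by -log|C_ij|.

    Edges with C_ij == 0 (infinite weight) are dropped.  Sequence-adjacent
    residues are eligible by default -- the analysis target here is a
    covalent linker pathway -- with ``exclude_sequence_neighbors`` to mimic
    conventions that drop them.
    """
    import warnings

    pers = contact_persistence(traj, corr.node_ids, cutoff=cutoff,
                               stride=stride, frames=frames)
    index = {n: i for i, n in enumerate(corr.node_ids)}
    g = nx.Graph()
    g.add_nodes_from(corr.node_ids)
    for (a, b), p in pers.items():
        if p < persistence:
            continue
        if exclude_sequence_neighbors and a[0] == b[0] and abs(a[1] - b[1]) == 1:
            continue
        c = corr.C[index[a], index[b]]
        if c == 0.0:
            continue
        g.add_edge(a, b, weight=-math.log(abs(c)), C=float(c), persistence=float(p))
    if g.number_of_edges() == 0:
        warnings.warn("no residue pair passed the contact persistence filter; "
                      "graph has no edges", stacklevel=2)
    return ContactGraph(g, distance_cutoff=cutoff, persistence_threshold=persistence)


def _lex_dijkstra(g: nx.Graph, source: NodeId, target: NodeId) -> tuple[float, list[NodeId]]:
    """Shortest path with deterministic tie-break: among equal-length paths the
    lexicographically smallest node sequence wins."""
    best: dict[NodeId, tuple[float, tuple]] = {}
    heap: list[tuple[float, tuple, NodeId]] = [(0.0, (source,), source)]
    while heap:
        dist, path, node = heapq.heappop(heap)
        if node == target:
            return dist, list(path)
        cur = best.get(node)
        if cur is not None and (cur[0] < dist - 1e-12 or
                                (abs(cur[0] - dist) <= 1e-12 and cur[1] <= path)):
            continue
        best[node] = (dist, path)
        for nb in g.neighbors(node):
            if nb in path:
                continue
            nd = dist + g[node][nb]["weight"]
            heapq.heappush(heap, (nd, path + (nb,), nb))
    raise NoPathError(f"no path between {source} and {target}")


def optimal_path(graph: ContactGraph, source: NodeId, target: NodeId) -> CouplingPath:
    """Minimum-total-weight simple path; ties broken lexicographically."""
    g = graph.graph
    for node in (source, target):
        if node not in g:
            raise KeyError(f"node {node} not in graph")
    if source == target:
        return CouplingPath([source], 0.0, rank=1)
    if not nx.has_path(g, source, target):
        comp_s = sorted(nx.node_connected_component(g, source))
        comp_t = sorted(nx.node_connected_component(g, target))
        raise NoPathError(
            f"{source} and {target} are disconnected "
            f"(components of size {len(comp_s)} and {len(comp_t)})")
    dist, nodes = _lex_dijkstra(g, source, target)
    return CouplingPath(nodes, dist, rank=1)


def _path_length(g: nx.Graph, nodes: list[NodeId]) -> float:
    return sum(g[a][b]["weight"] for a, b in zip(nodes[:-1], nodes[1:]))


def suboptimal_paths(graph: ContactGraph, source: NodeId, target: NodeId,
                     k: int = 10) -> list[CouplingPath]:
    """The optimal plus k suboptimal loopless paths, ordered by total length
    then lexicographically. Returns all existing paths when fewer than k+1
    simple paths exist."""
    g = graph.graph
    if source == target:
        return [CouplingPath([source], 0.0, rank=1)]
    if not nx.has_path(g, source, target):
        raise NoPathError(f"no path between {source} and {target}")
    want = k + 1
    collected: list[tuple[float, list[NodeId]]] = []
    gen = nx.shortest_simple_paths(g, source, target, weight="weight")
    for nodes in gen:
        length = _path_length(g, nodes)
        if len(collected) >= want and length > collected[want - 1][0] + 1e-12:
            break
        collected.append((length, nodes))
    collected.sort(key=lambda t: (t[0], tuple(t[1])))
    collected = collected[:want]
    if len(collected) < want:
        import warnings
        warnings.warn(f"only {len(collected)} simple path(s) exist between "
                      f"{source} and {target}; requested {want}", stacklevel=2)
    return [CouplingPath(nodes, length, rank=r + 1)
            for r, (length, nodes) in enumerate(collected)]


def path_domain_fraction(paths: list[CouplingPath], node_set: set[NodeId]) -> float:
    """Fraction of paths visiting at least one node of ``node_set``."""
    if not paths:
        raise ValueError("paths must be non-empty")
    hit = sum(1 for p in paths if any(n in node_set for n in p.nodes))
    return hit / len(paths)


def all_pairs_distances(graph: ContactGraph, method: str = "floyd-warshall"
                        ) -> dict[NodeId, dict[NodeId, float]]:
    """All-pairs shortest-path lengths via Floyd-Warshall or Dijkstra.

    The two methods must agree on any graph; exposing both makes the
    cross-algorithm consistency testable.
    """
    g = graph.graph
    if method == "floyd-warshall":
        return {a: dict(d) for a, d in nx.floyd_warshall(g, weight="weight").items()}
    if method == "dijkstra":
        return {a: dict(d) for a, d in nx.all_pairs_dijkstra_path_length(g, weight="weight")}
    raise ValueError(f"unknown method {method!r}")


def write_paths_json(paths: list[CouplingPath], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in paths], fh, indent=1)


def paths_to_frame(paths: list[CouplingPath]) -> pd.DataFrame:
    rows = []
    for p in paths:
        for step, (c, r) in enumerate(p.nodes):
            rows.append({"rank": p.rank, "step": step, "chain": c, "resid": r,
                         "total_length": p.total_length})
    return pd.DataFrame(rows)
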