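"""Weighted graph metrics for thresholded connectomes.

The battery computed here is: per node -- strength, betweenness
centrality (BC), Onnela weighted clustering coefficient (CC), average
shortest path length (APL) and participation coefficient (PC); per
network -- small-worldness sigma, global efficiency and global
clustering.

Path-based metrics convert streamline-count weights to lengths via
length = 1/weight, the usual convention for count-weighted connectomes:
a stronger connection is a shorter edge.  Shortest paths are exact
(Dijkstra per source); betweenness is the unnormalized Brandes variant
that splits credit across all tied shortest paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra, floyd_warshall

from .io import ConnectivityMatrix
from .nulls import NullEnsembleConfig, null_ensemble


class DisconnectedGraphError(ValueError):
    pass


class UnreachablePairError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise shortest-path lengths; unreachable pairs are inf with reachable=False."""

    d: np.ndarray
    reachable: np.ndarray

    @property
    def n(self) -> int:
        return self.d.shape[0]

    @property
    def fully_connected(self) -> bool:
        off = ~np.eye(self.n, dtype=bool)
        return bool(self.reachable[off].all())


@dataclass(frozen=True)
class ModulePartition:
    """Community id per node (0-based, arbitrary labels)."""

    assignment: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if a.ndim != 1 or len(a) == 0:
            raise ValueError("assignment must be a nonempty 1-d array")
        object.__setattr__(self, "assignment", a)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.assignment))


def node_strength(m: ConnectivityMatrix) -> np.ndarray:
    """Sum of edge weights incident to each node."""
    return m.weights.sum(axis=1)


def weight_to_length(m: ConnectivityMatrix) -> np.ndarray:
    """length_ij = 1/w_ij for present edges, inf otherwise."""
    with np.errstate(divide="ignore"):
        lengths = np.where(m.weights > 0, 1.0 / m.weights, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def all_pairs_shortest_paths(lengths: np.ndarray) -> DistanceMatrix:
    """Exact all-pairs shortest paths on a symmetric nonnegative length matrix.

    Dense Floyd-Warshall for small networks (faster at connectome scale),
    Dijkstra per source on a sparse graph for larger ones; both exact.
    """
    n = lengths.shape[0]
    if n <= 256:
        d = floyd_warshall(np.ascontiguousarray(lengths), directed=False)
    else:
        iu, ju = np.triu_indices(n, 1)
        finite = np.isfinite(lengths[iu, ju])
        graph = csr_matrix(
            (lengths[iu, ju][finite], (iu[finite], ju[finite])), shape=(n, n)
        )
        d = dijkstra(graph, directed=False)
    return DistanceMatrix(d=d, reachable=np.isfinite(d))


def nodal_apl(dist: DistanceMatrix, policy: str = "strict") -> np.ndarray:
    """Mean shortest-path distance from each node to all others.

    ``policy="strict"`` raises when any pair is unreachable (the
    guarantee inside a selected threshold range); ``"reachable"``
    averages over reachable partners only.
    """
    n = dist.n
    off = ~np.eye(n, dtype=bool)
    if policy == "strict":
        if not dist.fully_connected:
            bad = np.argwhere(~dist.reachable & off)[0]
            raise UnreachablePairError(
                f"nodes {bad[0]} and {bad[1]} are mutually unreachable (strict APL policy)"
            )
        return dist.d.sum(axis=1) / (n - 1)
    if policy == "reachable":
        reach = dist.reachable & off
        counts = reach.sum(axis=1)
        sums = np.where(reach, dist.d, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    raise ValueError(f"unknown APL policy {policy!r}")


def characteristic_path_length(dist: DistanceMatrix) -> float:
    """Mean distance over reachable ordered pairs (i != j)."""
    off = ~np.eye(dist.n, dtype=bool)
    reach = dist.reachable & off
    if not reach.any():
        raise DisconnectedGraphError("no reachable pairs")
    return float(dist.d[reach].mean())


def global_efficiency(dist: DistanceMatrix) -> float:
    """Mean inverse distance over ordered pairs; unreachable pairs contribute 0."""
    n = dist.n
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(dist.d)
    reach = dist.reachable & off
    inv[reach] = 1.0 / dist.d[reach]
    return float(inv[off].mean())


def betweenness_centrality(m: ConnectivityMatrix) -> np.ndarray:
    """Unnormalized weighted betweenness (Brandes) on lengths = 1/w.

    Each unordered pair of endpoints contributes a total of 1, split
    equally across its tied shortest paths.
    """
    n = m.n
    iu, ju = np.triu_indices(n, 1)
    mask = m.weights[iu, ju] > 0
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    if not edges:
        return np.zeros(n)
    lengths = (1.0 / m.weights[iu[mask], ju[mask]]).tolist()
    g = ig.Graph(n, edges)
    return np.asarray(g.betweenness(weights=lengths), dtype=float)


def weighted_clustering(m: ConnectivityMatrix) -> np.ndarray:
    """Onnela weighted clustering coefficient.

    C_i = (1/(k_i(k_i-1))) * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) summed
    over ordered neighbor pairs, with weights normalized by the network
    maximum (w' = w / max w) and k_i the binary degree; C_i = 0 for
    k_i < 2.
    """
    w = m.weights
    wmax = w.max()
    if wmax == 0:
        return np.zeros(m.n)
    what = np.cbrt(w / wmax)
    num = np.diagonal(what @ what @ what)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, num / np.maximum(denom, 1), 0.0)
    return c


def global_clustering(m: ConnectivityMatrix) -> float:
    """Mean of the nodal Onnela clustering coefficients."""
    return float(weighted_clustering(m).mean())


def participation_coefficient(m: ConnectivityMatrix, partition: ModulePartition) -> np.ndarray:
    """PC_i = 1 - sum_s (kappa_is / k_i)^2 over communities s; 0 for isolated nodes."""
    a = partition.assignment
    if len(a) != m.n:
        raise ValueError("partition does not cover all nodes")
    strength = m.weights.sum(axis=1)
    pc = np.zeros(m.n)
    nz = strength > 0
    comms = np.unique(a)
    kappa = np.stack([m.weights[:, a == c].sum(axis=1) for c in comms], axis=1)
    frac = kappa[nz] / strength[nz, None]
    pc[nz] = 1.0 - (frac**2).sum(axis=1)
    return pc


def modularity_partition(m: ConnectivityMatrix, seed: int = 0) -> ModulePartition:
    """Modularity-maximizing (Louvain) partition of a weighted matrix.

    Used once on a reference matrix (e.g. the control-group mean at the
    midpoint density) and then frozen, so that participation
    coefficients are comparable across subjects and thresholds.
    """
    g = nx.from_numpy_array(m.weights)
    communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
    assignment = np.empty(m.n, dtype=int)
    for cid, members in enumerate(communities):
        for node in members:
            assignment[node] = cid
    return ModulePartition(assignment)


def small_world_sigma(
    m: ConnectivityMatrix,
    n_nulls: int = 20,
    seed: int = 0,
    *,
    swaps_per_edge: int = 10,
    config: NullEnsembleConfig | None = None,
) -> float:
    """Small-worldness sigma = (C/C_null) / (L/L_null).

    C is the global (mean Onnela) clustering, L the characteristic path
    length over reachable ordered pairs; the null values are means over
    an ensemble of degree-preserving rewired surrogates with the
    original weights shuffled onto the rewired topology.  Values above 1
    indicate small-world organization.  The input network must be
    connected; surrogates are allowed to fragment (their L is a
    reachable-pair mean).
    """
    if config is None:
        config = NullEnsembleConfig(n_nulls=n_nulls, swaps_per_edge=swaps_per_edge, seed=seed)
    dist = all_pairs_shortest_paths(weight_to_length(m))
    if not dist.fully_connected:
        raise DisconnectedGraphError("sigma requires a connected network")
    c_obs = global_clustering(m)
    l_obs = characteristic_path_length(dist)
    c_nulls = []
    l_nulls = []
    for surrogate in null_ensemble(m, config):
        c_nulls.append(global_clustering(surrogate))
        d_null = all_pairs_shortest_paths(weight_to_length(surrogate))
        l_nulls.append(characteristic_path_length(d_null))
    c_null = float(np.mean(c_nulls))
    l_null = float(np.mean(l_nulls))
    if c_null == 0 or l_null == 0:
        raise ValueError("degenerate null ensemble (zero clustering or path length)")
    return (c_obs / c_null) / (l_obs / l_null)
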