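"""Degree-preserving randomized surrogate networks.

Surrogates for the small-worldness ratio are built by Maslov-Sneppen
double-edge swaps on the binary topology (swaps creating self-loops or
multi-edges are rejected), after which the original multiset of edge
weights is randomly permuted onto the rewired edge set.  The binary
degree sequence is preserved exactly; node strength in general is not.
Connectivity of surrogates is not enforced -- the characteristic path
length of a fragmented surrogate is taken over reachable pairs and the
event is logged.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph as ig
import numpy as np

from .io import ConnectivityMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullEnsembleConfig:
    n_nulls: int = 20
    swaps_per_edge: int = 10
    max_retries: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1 or self.swaps_per_edge < 1 or self.max_retries < 1:
            raise ValueError("all null-ensemble settings must be positive")


def _draw_seed(config: NullEnsembleConfig, draw_index: int, retry: int = 0) -> int:
    ss = np.random.SeedSequence([config.seed, draw_index, retry])
    return int(ss.generate_state(1)[0] % 2**31)


def degree_preserving_rewire(
    m: ConnectivityMatrix, config: NullEnsembleConfig, draw_index: int = 0
) -> ConnectivityMatrix:
    """One rewired surrogate, reproducible from (config.seed, draw_index).

    Attempts ``swaps_per_edge * |E|`` double-edge swaps.  When the
    topology admits no valid swap at all (e.g. a triangle), the edge set
    comes back unchanged and only the weights are shuffled.
    """
    n = m.n
    iu, ju = np.triu_indices(n, 1)
    mask = m.weights[iu, ju] > 0
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    weights = m.weights[iu[mask], ju[mask]]

    seed = _draw_seed(config, draw_index)
    g = ig.Graph(n, edges)
    random.seed(seed)  # python-igraph delegates its RNG to the random module
    g.rewire(config.swaps_per_edge * n_edges)
    new_edges = g.get_edgelist()
    if new_edges == edges and n_edges > 3:
        log.warning("rewire left the topology unchanged (draw %d)", draw_index)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_edges)
    w = np.zeros_like(m.weights)
    for (a, b), wv in zip(new_edges, weights[perm]):
        w[a, b] = wv
        w[b, a] = wv
    return ConnectivityMatrix(w, m.parcellation)


def null_ensemble(m: ConnectivityMatrix, config: NullEnsembleConfig) -> list[ConnectivityMatrix]:
    """``config.n_nulls`` independent surrogates."""
    return [degree_preserving_rewire(m, config, i) for i in range(config.n_nulls)]
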