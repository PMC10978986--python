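"""Markov clustering (MCL) of association graphs, and node centralities.

MCL simulates flow on the graph: a column-stochastic transition matrix is
alternately *expanded* (matrix power, default 2) and *inflated*
(elementwise power, default 1.5, followed by column renormalization) with
pruning of vanishing entries, until the process converges to a
doubly-idempotent attractor matrix. Rows of attractor nodes (nonzero
diagonal) define the clusters; overlapping attractor rows are merged.

Because flow interpretation requires non-negative similarities, negative
edges of a signed association network are dropped before clustering by
default (``negative="drop"``); ``negative="abs"`` uses absolute weights
instead. Self-loops are added with the node's maximal incident edge
weight, a standard regularization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable

import networkx as nx
import numpy as np

__all__ = ["MCLConfig", "mcl_cluster", "closeness_centrality"]


@dataclass(frozen=True)
class MCLConfig:
    inflation: float = 1.5
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 200
    convergence_tol: float = 1e-8
    self_loop: str = "max"  # max incident weight; "unit" uses 1.0

    def __post_init__(self) -> None:
        if self.inflation <= 1.0:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


class MCLConvergenceError(RuntimeError):
    def __init__(self, iterations: int, change: float):
        super().__init__(
            f"MCL did not converge within {iterations} iterations "
            f"(last change {change:.3e})"
        )
        self.iterations = iterations
        self.change = change


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0.0] = 1.0
    return m / sums


def mcl_cluster(
    graph: nx.Graph,
    cfg: MCLConfig = MCLConfig(),
    weight: str = "weight",
    negative: str = "drop",
) -> tuple[list[set], set]:
    """Cluster a weighted graph with the Markov clustering algorithm.

    Returns ``(communities, singletons)`` where communities are node sets
    of size >= 2 and singletons the remaining nodes. Deterministic: nodes
    are processed in sorted order.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if negative not in ("drop", "abs"):
        raise ValueError(f"unknown negative-edge policy: {negative}")

    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, d in graph.edges(data=True):
        w = float(d.get(weight, 1.0))
        if w < 0:
            if negative == "drop":
                continue
            w = abs(w)
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w

    # self-loop regularization
    for i in range(n):
        inc = m[i].max()
        m[i, i] = inc if (cfg.self_loop == "max" and inc > 0) else 1.0

    m = _normalize_columns(m)
    change = np.inf
    for _ in range(cfg.max_iter):
        prev = m
        m = np.linalg.matrix_power(m, cfg.expansion)
        m = m**cfg.inflation
        m[m < cfg.prune_threshold] = 0.0
        m = _normalize_columns(m)
        change = float(np.abs(m - prev).max())
        if change < cfg.convergence_tol:
            break
    else:
        raise MCLConvergenceError(cfg.max_iter, change)

    # attractor rows -> clusters; merge overlapping rows
    clusters: list[set] = []
    for i in range(n):
        if m[i, i] > 0:
            members = {nodes[j] for j in np.nonzero(m[i])[0]}
            merged = False
            for c in clusters:
                if c & members:
                    c |= members
                    merged = True
                    break
            if not merged:
                clusters.append(members)
    # a node may still sit in two merged groups after late unions; resolve
    stable = False
    while not stable:
        stable = True
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters.pop(j)
                    stable = False
                    break
            if not stable:
                break

    assigned = set().union(*clusters) if clusters else set()
    singletons = {n_ for n_ in nodes if n_ not in assigned}
    communities = []
    for c in clusters:
        if len(c) >= 2:
            communities.append(c)
        else:
            singletons |= c
    communities.sort(key=lambda c: sorted(c)[0])
    return communities, singletons


def closeness_centrality(graph: nx.Graph, node: Hashable | None = None):
    """Closeness centrality with component normalization.

    For a node in a connected component of size ``n_c``, the value is
    ``(n_c - 1) / sum(shortest path lengths)`` with unit edge lengths;
    isolated nodes get 0. Returns a dict, or a float when ``node`` is
    given.
    """
    cc = nx.closeness_centrality(graph, wf_improved=False)
    if node is not None:
        if node not in graph:
            raise KeyError(f"node not in graph: {node!r}")
        return cc[node]
    return cc
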