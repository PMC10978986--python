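"""Direct-association network inference from CLR-transformed omics matrices.

A constraint-based (PC-stable style) procedure: starting from all
marginally significant genome-genome correlations, edges are pruned by
conditional-independence tests of increasing conditioning-set size
(up to ``max_k``) drawn from the current neighbourhoods of the edge's
endpoints. A partial correlation is declared significant by the Fisher
z-test, ``z = atanh(r) * sqrt(n - |S| - 3)`` against a two-sided normal.
Surviving edges are weighted by the partial correlation given the largest
conditioning set that last certified them, so the result contains only
direct associations with signed strengths.

Missing values (unobserved genome/sample cells) are handled by
pairwise-complete observations per test; a test requires at least
``n_obs_min`` shared observations, and an edge only exists if at least
one significant test certified it.

The procedure is deterministic given input order: nodes are iterated in
sorted order and conditioning subsets in sorted lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NetworkConfig",
    "fisher_z_test",
    "partial_correlation",
    "infer_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Inference parameters (FlashWeave-like sensitive mode defaults)."""

    alpha: float = 0.01
    max_k: int = 3
    n_obs_min: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_k < 0:
            raise ValueError("max_k must be >= 0")


def fisher_z_test(r: float, n: int, k: int, alpha: float) -> tuple[bool, float]:
    """Fisher z-transform significance test of a (partial) correlation.

    ``r`` is the sample (partial) correlation, ``n`` the number of
    observations and ``k`` the size of the conditioning set. Returns
    (significant, two-sided p-value).
    """
    dof = n - k - 3
    if dof <= 0:
        raise ValueError(f"insufficient observations: n - k - 3 = {dof}")
    r = float(np.clip(r, -0.9999999, 0.9999999))
    z = np.arctanh(r) * np.sqrt(dof)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return p < alpha, p


def _complete_rows(data: np.ndarray, cols: Sequence[int]) -> np.ndarray:
    sub = data[:, list(cols)]
    return sub[np.isfinite(sub).all(axis=1)]


def partial_correlation(
    data: np.ndarray, i: int, j: int, S: Sequence[int] = ()
) -> tuple[float, int]:
    """Partial correlation r_{ij.S} on pairwise-complete observations.

    ``data`` is observations x variables with NaN for missing cells.
    Computed by inverting the correlation matrix of ``{i, j} | S`` over
    rows complete in all involved variables. Returns (r, n_complete).
    With an empty conditioning set this is the plain Pearson correlation.
    """
    cols = [i, j, *S]
    rows = _complete_rows(data, cols)
    n = rows.shape[0]
    if n < len(cols) + 1:
        return np.nan, n
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(rows, rowvar=False)
    if not np.all(np.isfinite(corr)):
        return np.nan, n  # constant variable among {i,j} u S
    if not S:
        return float(corr[0, 1]), n
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        raise ValueError("singular conditioning set (collinear variables)")
    r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    return float(np.clip(r, -1.0, 1.0)), n


def infer_network(
    matrix: pd.DataFrame, cfg: NetworkConfig = NetworkConfig()
) -> nx.Graph:
    """Infer a signed direct-association network from a CLR matrix.

    Parameters
    ----------
    matrix : genomes x samples DataFrame, NaN marking unobserved cells
        (typically the output of :func:`ecometab.profiling.clr_transform`).
    cfg : test level, maximal conditioning-set size and minimum shared
        observations.

    Returns a :class:`networkx.Graph` whose edges carry ``weight`` (the
    partial correlation given the largest certifying conditioning set),
    ``cond_set`` (that conditioning set, as a tuple of genome ids) and
    ``p`` (its test p-value). Removed edges are logged in
    ``G.graph["audit"]`` as (g1, g2, cond_set, p) tuples.
    """
    if matrix.empty:
        raise ValueError("empty matrix")
    nodes = sorted(matrix.index)
    data = matrix.loc[nodes].T.to_numpy(dtype=float)  # samples x genomes
    idx = {g: pos for pos, g in enumerate(nodes)}

    G = nx.Graph()
    G.add_nodes_from(nodes)
    audit: list[tuple] = []
    G.graph["audit"] = audit

    # level 0: marginal correlations
    for g1, g2 in combinations(nodes, 2):
        r, n = partial_correlation(data, idx[g1], idx[g2])
        if not np.isfinite(r) or n < max(cfg.n_obs_min, 4):
            continue
        sig, p = fisher_z_test(r, n, 0, cfg.alpha)
        if sig:
            G.add_edge(g1, g2, weight=r, cond_set=(), p=p, _k=0)
        else:
            audit.append((g1, g2, (), p))

    # levels 1..max_k: PC-stable pruning with neighbourhood-restricted sets
    for k in range(1, cfg.max_k + 1):
        adjacency = {g: sorted(G.neighbors(g)) for g in nodes}
        for g1, g2 in sorted(G.edges()):
            g1, g2 = sorted((g1, g2))
            candidates = sorted(
                (set(adjacency[g1]) | set(adjacency[g2])) - {g1, g2}
            )
            if len(candidates) < k:
                continue
            removed = False
            for S in combinations(candidates, k):
                cols = tuple(idx[s] for s in S)
                try:
                    r, n = partial_correlation(data, idx[g1], idx[g2], cols)
                except ValueError:
                    continue  # singular conditioning: test not decidable
                if not np.isfinite(r) or n < max(cfg.n_obs_min, k + 4):
                    continue  # insufficient shared observations: skip
                sig, p = fisher_z_test(r, n, k, cfg.alpha)
                if not sig:
                    G.remove_edge(g1, g2)
                    audit.append((g1, g2, S, p))
                    removed = True
                    break
                # deeper certification: record strongest conditioning set
                if k > G.edges[g1, g2]["_k"]:
                    G.edges[g1, g2].update(weight=r, cond_set=S, p=p, _k=k)
            if removed:
                continue

    for _, _, attrs in G.edges(data=True):
        attrs.pop("_k", None)
    return G


def edge_table(G: nx.Graph) -> pd.DataFrame:
    """Edge list as a tidy table (g1, g2, weight, cond_set, p)."""
    rows = [
        {
            "g1": min(a, b),
            "g2": max(a, b),
            "weight": d["weight"],
            "cond_set": ",".join(d.get("cond_set", ())),
            "p": d.get("p", np.nan),
        }
        for a, b, d in G.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["g1", "g2", "weight", "cond_set", "p"]).sort_values(
        ["g1", "g2"], ignore_index=True
    )
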