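"""Genome catalogue services.

Quality classification of genomes recovered from isolates (WGS), single
cells (SAGs) and metagenome assemblies (MAGs); species-level dereplication
on precomputed ANI/alignment-coverage matrices; and phylogenetic-distance
services on domain trees joined at the root.

Quality classes follow the usual completeness/contamination gates used for
environmental genome catalogues:

* HQ  : completeness >= 0.90 and contamination <= 0.05
* MHQ : completeness >= 0.75 and contamination <= 0.10
* MQ  : completeness >= 0.50 and contamination <= 0.25
* LQ  : everything else (kept in outputs, excluded from downstream stages)

Dereplication is the standard two-step single-linkage scheme: coarse
components at >=90% ANI over >=60% aligned coverage, then fine components
at >=95% ANI within each coarse component. The representative of each
species cluster maximizes ``completeness - 5 * contamination`` with ties
broken by genome length then lexicographic id.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "GenomeRecord",
    "SpeciesCluster",
    "classify_quality",
    "completeness_corrected",
    "dereplicate",
    "join_domain_trees",
    "read_newick",
    "write_newick",
    "tip_distance_matrix",
    "patristic_distance",
    "mean_community_pd",
    "QUALITY_ORDER",
]

QUALITY_ORDER = ("HQ", "MHQ", "MQ", "LQ")

#: Default weight of contamination in the representative quality score.
CONTAMINATION_WEIGHT = 5.0

#: Default total branch length bridging the bacterial and archaeal subtrees.
DOMAIN_BRIDGE_LENGTH = 0.122


@dataclass(frozen=True)
class GenomeRecord:
    """One species-level genome and its quality metadata."""

    genome_id: str
    completeness: float
    contamination: float
    genome_length: int
    n_cds: int = 0
    domain: str = "Bacteria"
    source_class: str = "MAG"

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError(f"completeness out of [0,1]: {self.completeness}")
        if self.contamination < 0.0:
            raise ValueError(f"negative contamination: {self.contamination}")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")

    @property
    def quality_class(self) -> str:
        return classify_quality(self.completeness, self.contamination)

    @property
    def quality_score(self) -> float:
        return self.completeness - CONTAMINATION_WEIGHT * self.contamination


@dataclass(frozen=True)
class SpeciesCluster:
    """A species-level cluster with a chosen representative genome."""

    cluster_id: str
    member_ids: frozenset
    representative_id: str

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")


def classify_quality(completeness: float, contamination: float) -> str:
    """Classify a genome by completeness/contamination into HQ/MHQ/MQ/LQ.

    Both arguments are fractions; contamination may exceed 1 for heavily
    chimeric bins. Boundaries are inclusive (``>=`` / ``<=``).
    """
    if not 0.0 <= completeness <= 1.0:
        raise ValueError(f"completeness out of [0,1]: {completeness}")
    if contamination < 0.0:
        raise ValueError(f"negative contamination: {contamination}")
    if completeness >= 0.90 and contamination <= 0.05:
        return "HQ"
    if completeness >= 0.75 and contamination <= 0.10:
        return "MHQ"
    if completeness >= 0.50 and contamination <= 0.25:
        return "MQ"
    return "LQ"


def completeness_corrected(value: float, completeness: float) -> float:
    """Correct a genome size or CDS count for incompleteness (value / completeness)."""
    if completeness <= 0:
        raise ValueError("completeness must be > 0 for correction")
    return value / completeness


def _threshold_components(
    ids: Sequence[str],
    ani: pd.DataFrame,
    cov: pd.DataFrame,
    min_ani: float,
    min_cov: float,
) -> list[list[str]]:
    g = nx.Graph()
    g.add_nodes_from(ids)
    for a, b in combinations(ids, 2):
        if ani.at[a, b] >= min_ani and cov.at[a, b] >= min_cov:
            g.add_edge(a, b)
    return [sorted(c) for c in nx.connected_components(g)]


def dereplicate(
    ani: pd.DataFrame,
    cov: pd.DataFrame,
    genomes: Iterable[GenomeRecord],
    coarse_ani: float = 0.90,
    fine_ani: float = 0.95,
    min_cov: float = 0.60,
    contamination_weight: float = CONTAMINATION_WEIGHT,
) -> list[SpeciesCluster]:
    """Two-step single-linkage species dereplication.

    Coarse connected components on ``ani >= coarse_ani & cov >= min_cov``
    then, inside each coarse component, fine components on
    ``ani >= fine_ani & cov >= min_cov``. Each fine component is one
    species cluster; its representative maximizes
    ``completeness - contamination_weight * contamination``, ties broken
    by larger genome then lexicographically smaller id.
    """
    records = {g.genome_id: g for g in genomes}
    ids = sorted(records)
    for name, m in (("ani", ani), ("cov", cov)):
        missing = set(ids) - set(m.index)
        if missing:
            raise ValueError(f"{name} matrix missing genomes: {sorted(missing)}")
        sub = m.loc[ids, ids]
        if not np.allclose(sub.values, sub.values.T, atol=1e-9):
            raise ValueError(f"{name} matrix is not symmetric")

    clusters: list[SpeciesCluster] = []
    n = 0
    for coarse in _threshold_components(ids, ani, cov, coarse_ani, min_cov):
        for fine in _threshold_components(coarse, ani, cov, fine_ani, min_cov):
            n += 1
            rep = max(
                fine,
                key=lambda gid: (
                    records[gid].completeness
                    - contamination_weight * records[gid].contamination,
                    records[gid].genome_length,
                    # lexicographically smallest id wins the final tie
                    tuple(-ord(c) for c in gid),
                ),
            )
            clusters.append(
                SpeciesCluster(f"cluster_{n:04d}", frozenset(fine), rep)
            )
    return clusters


# ---------------------------------------------------------------------------
# Phylogenetic-distance services
# ---------------------------------------------------------------------------


def read_newick(source: str) -> TreeNode:
    """Read a Newick tree from a string or a file path."""
    if "(" in source or ";" in source:
        return TreeNode.read(io.StringIO(source), format="newick")
    return TreeNode.read(source, format="newick")


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def join_domain_trees(
    bacteria: TreeNode | str,
    archaea: TreeNode | str,
    bridge: float = DOMAIN_BRIDGE_LENGTH,
) -> TreeNode:
    """Join the bacterial and archaeal subtrees under a new root.

    The two subtree roots are attached by branches of length ``bridge / 2``
    each, so that any inter-domain leaf pair gains exactly ``bridge`` of
    path length on top of its intra-subtree depths. Intra-domain patristic
    distances are unchanged.
    """
    t1 = read_newick(bacteria) if isinstance(bacteria, str) else bacteria.copy()
    t2 = read_newick(archaea) if isinstance(archaea, str) else archaea.copy()
    leaves1 = {t.name for t in t1.tips()} or {t1.name}
    leaves2 = {t.name for t in t2.tips()} or {t2.name}
    overlap = leaves1 & leaves2
    if overlap:
        raise ValueError(f"overlapping leaf names across domains: {sorted(overlap)}")
    t1.length = bridge / 2.0
    t2.length = bridge / 2.0
    root = TreeNode(children=[t1, t2])
    return root


def tip_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """All pairwise patristic distances between leaves, as a DistanceMatrix."""
    return tree.tip_tip_distances()


def patristic_distance(tree: TreeNode, g1: str, g2: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    if g1 == g2:
        # still validate that the leaf exists
        tree.find(g1)
        return 0.0
    try:
        a = tree.find(g1)
        b = tree.find(g2)
    except Exception as exc:  # skbio raises MissingNodeError
        raise KeyError(f"unknown leaf: {exc}") from exc
    return float(a.distance(b))


def mean_community_pd(
    tree: TreeNode | DistanceMatrix, members: Iterable[str]
) -> float:
    """Mean pairwise patristic distance over all unordered member pairs."""
    ids = sorted(set(members))
    if len(ids) < 2:
        raise ValueError("community must have >= 2 members")
    if isinstance(tree, DistanceMatrix):
        dm = tree
        dists = [dm[a, b] for a, b in combinations(ids, 2)]
    else:
        dists = [patristic_distance(tree, a, b) for a, b in combinations(ids, 2)]
    return float(np.mean(dists))
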