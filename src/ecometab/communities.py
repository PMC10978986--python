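"""Null-model community typing and community-level functional statistics.

Co-active communities are contrasted against randomly assembled
communities sampled from the same genome pool. Two null quantiles define
four community types on the (mean phylogenetic distance, normalized
cross-feeding score) plane:

* **LPD** (low phylogenetic distance): mean pairwise patristic distance
  below the null 5th percentile;
* **HCP** (high cross-feeding potential): normalized smetana score above
  the null 95th percentile;

giving the exhaustive, mutually exclusive labels LPD-LCP, LPD-HCP,
HPD-LCP and HPD-HCP. Random communities classify as HPD-LCP with
probability ~0.95^2 by construction.

Functional statistics include a bias-corrected Gini coefficient of the
per-member "functional capital" (the number of community-occurring KOs a
genome carries; 0 = perfect functional overlap, 1 = a single member
holds every detected function), KO-based Jaccard distances, per-category
exchange profiles, Mann-Whitney tests with Benjamini-Hochberg correction
across metabolites, and a non-metric MDS ordination of exchange
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from .metabolism import PairwiseScore, categorize_metabolites

__all__ = [
    "NullThresholds",
    "TypingResult",
    "COMMUNITY_TYPES",
    "sample_random_communities",
    "compute_null_thresholds",
    "classify_community",
    "functional_capitals",
    "functional_gini",
    "functional_jaccard",
    "exchange_category_profile",
    "per_metabolite_tests",
    "significance_stars",
    "nmds_ordination",
    "donor_summaries",
]

COMMUNITY_TYPES = ("LPD-LCP", "LPD-HCP", "HPD-LCP", "HPD-HCP")


@dataclass(frozen=True)
class NullThresholds:
    """Null quantiles from random communities (linear-interpolation quantiles)."""

    pd_q05: float
    score_q95: float
    n_random: int

    def __post_init__(self) -> None:
        if self.n_random < 30:
            raise ValueError("null thresholds need >= 30 random communities")


@dataclass(frozen=True)
class TypingResult:
    community_id: str
    mean_pd: float
    normalized_score: float
    gini: float
    type: str


def sample_random_communities(
    pool: Sequence[str],
    sizes: Sequence[int],
    n: int,
    seed: int = 0,
) -> list[frozenset]:
    """Random communities: uniform sampling without replacement from the pool.

    Community sizes are resampled from the observed co-active size
    multiset ``sizes``. Deterministic under seed.
    """
    pool = sorted(set(pool))
    if max(sizes) > len(pool):
        raise ValueError("community size exceeds pool size")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        size = int(rng.choice(sizes))
        out.append(frozenset(rng.choice(pool, size, replace=False)))
    return out


def compute_null_thresholds(
    mean_pds: Sequence[float], scores: Sequence[float]
) -> NullThresholds:
    if len(mean_pds) != len(scores):
        raise ValueError("mean_pds and scores must be paired per community")
    return NullThresholds(
        pd_q05=float(np.quantile(mean_pds, 0.05, method="linear")),
        score_q95=float(np.quantile(scores, 0.95, method="linear")),
        n_random=len(mean_pds),
    )


def classify_community(
    mean_pd: float, normalized_score: float, thr: NullThresholds
) -> str:
    """Quadrant label: LPD iff pd < null q05, HCP iff score > null q95."""
    pd_part = "LPD" if mean_pd < thr.pd_q05 else "HPD"
    cp_part = "HCP" if normalized_score > thr.score_q95 else "LCP"
    return f"{pd_part}-{cp_part}"


def functional_capitals(
    members: Iterable[str], ko_sets: Mapping[str, set]
) -> pd.Series:
    """Per-member functional capital: community-occurring KOs the member holds."""
    members = sorted(set(members))
    occurring: set = set()
    for g in members:
        occurring |= set(ko_sets.get(g, ()))
    return pd.Series({g: len(occurring & set(ko_sets.get(g, ()))) for g in members})


def functional_gini(capitals: Sequence[float], corrected: bool = True) -> float:
    """Gini coefficient of functional capitals across community members.

    The bias-corrected denominator ``2 n (n-1) mean`` makes the verbal
    endpoints exactly attainable: equal capitals give 0 and a single
    holder gives 1. ``corrected=False`` uses the raw ``2 n^2 mean``.
    """
    x = np.asarray(list(capitals), dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 members")
    if (x < 0).any():
        raise ValueError("capitals must be non-negative")
    mean = x.mean()
    if mean == 0:
        raise ValueError("all capitals are zero")
    diff = np.abs(x[:, None] - x[None, :]).sum()
    n = x.size
    den = 2 * n * (n - 1) * mean if corrected else 2 * n * n * mean
    return float(diff / den)


def functional_jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard distance 1 - |A & B| / |A | B| between two KO sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("both sets empty")
    return 1.0 - len(a & b) / len(union)


def expressed_ko_sets(
    detection: pd.DataFrame, min_samples: int = 10
) -> dict[str, set]:
    """Restrict per-genome KO sets to KOs detected in >= min_samples samples.

    ``detection`` is a long table (genome_id, ko_id, n_samples_detected).
    """
    keep = detection[detection["n_samples_detected"] >= min_samples]
    return {g: set(sub["ko_id"]) for g, sub in keep.groupby("genome_id")}


def exchange_category_profile(
    records_by_community: Mapping[str, Sequence[PairwiseScore]],
    category_map: Mapping[str, str],
) -> pd.DataFrame:
    """Community x category matrix of summed smetana scores.

    Metabolites missing from the map land in the "uncategorized" column;
    row sums equal each community's smetana sum score.
    """
    rows = {}
    for cid, records in records_by_community.items():
        cats = categorize_metabolites([r.metabolite for r in records], category_map)
        acc: dict[str, float] = {}
        for r in records:
            acc[cats[r.metabolite]] = acc.get(cats[r.metabolite], 0.0) + r.smetana
        rows[cid] = acc
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return out.sort_index().sort_index(axis=1)


def significance_stars(p: float) -> str:
    """Star convention: **** p<=1e-4, *** <=1e-3, ** <=1e-2, * <=0.05, ns."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 5e-2:
        return "*"
    return "ns"


def per_metabolite_tests(
    scores: pd.DataFrame,
    groups: Mapping[str, str],
    min_group_n: int = 3,
) -> pd.DataFrame:
    """Two-group Mann-Whitney tests per metabolite with BH correction.

    ``scores`` is a community x metabolite matrix (e.g. summed smetana
    per metabolite); ``groups`` maps community id -> group label (exactly
    two labels required). Degenerate metabolites (all-identical values)
    are reported with p = 1.
    """
    labels = pd.Series(groups).reindex(scores.index)
    uniq = sorted(labels.dropna().unique())
    if len(uniq) != 2:
        raise ValueError("exactly two group labels required")
    ga = scores.loc[labels == uniq[0]]
    gb = scores.loc[labels == uniq[1]]
    if len(ga) < min_group_n or len(gb) < min_group_n:
        raise ValueError(f"each group needs >= {min_group_n} communities")
    rows = []
    for met in scores.columns:
        a, b = ga[met].values, gb[met].values
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            u, p = np.nan, 1.0
        else:
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"metabolite": met, "u_statistic": u, "p_value": p})
    out = pd.DataFrame(rows).set_index("metabolite")
    out["p_bh"] = multipletests(out["p_value"].values, method="fdr_bh")[1]
    out["stars"] = out["p_bh"].map(significance_stars)
    return out


def nmds_ordination(
    matrix: pd.DataFrame, seed: int = 0, dims: int = 2, n_init: int = 8
) -> tuple[pd.DataFrame, float]:
    """Non-metric MDS of community exchange profiles on Bray-Curtis distances.

    Returns the 2-D coordinates and the final (normalized) stress.
    Deterministic under seed.
    """
    if len(matrix) < 4:
        raise ValueError("NMDS needs >= 4 communities")
    if (matrix.sum(axis=1) == 0).any():
        raise ValueError("all-zero exchange rows cannot be ordinated")
    dist = squareform(pdist(matrix.values, metric="braycurtis"))
    mds = MDS(
        n_components=dims,
        metric_mds=False,
        metric="precomputed",
        init="random",
        random_state=int(seed),
        n_init=n_init,
        normalized_stress=True,
        max_iter=500,
    )
    coords = mds.fit_transform(dist)
    out = pd.DataFrame(coords, index=matrix.index, columns=[f"dim{i+1}" for i in range(dims)])
    return out, float(mds.stress_)


def donor_summaries(
    centrality: Mapping[str, float],
    genome_sizes: Mapping[str, float],
    records: Sequence[PairwiseScore],
    genomes: Iterable[str],
    categories: Mapping[str, str] | None = None,
    restrict_to: Iterable[str] | None = None,
) -> dict:
    """Compare donor versus non-donor genomes on centrality and genome size.

    A donor is any genome appearing as donor in >= 1 cross-feeding record
    (optionally restricted to metabolite categories in ``restrict_to``
    using ``categories``). Returns Mann-Whitney results (two-sided) for
    closeness centrality and completeness-corrected genome size, or a
    skip notice when one side is empty.
    """
    genomes = sorted(set(genomes))
    recs = records
    if restrict_to is not None:
        if categories is None:
            raise ValueError("restrict_to requires a category map")
        wanted = set(restrict_to)
        cats = categorize_metabolites([r.metabolite for r in records], categories)
        recs = [r for r in records if cats[r.metabolite] in wanted]
    donors = sorted({r.donor for r in recs} & set(genomes))
    non_donors = sorted(set(genomes) - set(donors))
    if not donors or not non_donors:
        return {"skipped": True, "reason": "need both donors and non-donors"}

    out: dict = {"skipped": False, "donors": donors, "non_donors": non_donors}
    for name, values in (("centrality", centrality), ("genome_size", genome_sizes)):
        a = [values[g] for g in donors]
        b = [values[g] for g in non_donors]
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        out[name] = {
            "u_statistic": float(u),
            "p_value": float(p),
            "donor_median": float(np.median(a)),
            "non_donor_median": float(np.median(b)),
        }
    raw = [out["centrality"]["p_value"], out["genome_size"]["p_value"]]
    corrected = multipletests(raw, method="bonferroni")[1]
    out["centrality"]["p_corrected"] = float(corrected[0])
    out["genome_size"]["p_corrected"] = float(corrected[1])
    return out
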