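"""End-to-end orchestration on synthetic worlds, plus evaluation protocols.

``run_world`` chains the full analysis on a seeded synthetic world:
coverage profiles with planted co-active communities -> detection and
activity matrices -> CLR -> direct-association network -> Markov
clustering -> toy metabolic models with planted obligate cross-feedings
-> community minimal media and pairwise cross-feeding scores -> null
-model community typing. The returned report carries both the
intermediate artifacts and recovery metrics against the planted truth.

The module also hosts the smaller evaluation protocols (filter fidelity,
scaling-law recovery, network calibration) shared by the test suite and
the reproduction script.

Problem sizes here are deliberately desk-scale: three planted
communities of three genomes each among eighteen genomes and 48 samples,
which matches the regime where single-latent-factor communities are
identifiable by partial-correlation pruning (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import rand_score

from . import catalog, communities, mcl, metabolism, network, profiling, scaling, synthetic

__all__ = [
    "WorldConfig",
    "WorldReport",
    "run_world",
    "filter_fidelity",
    "scaling_slope_recovery",
    "enrichment_scan_experiment",
    "chain_recovery_rate",
    "noise_edge_mean",
]


@dataclass(frozen=True)
class WorldConfig:
    n_communities: int = 3
    community_size: int = 3
    n_background: int = 9
    n_samples: int = 48
    support_size: int = 40
    noise: float = 0.25
    alpha: float = 0.01
    max_k: int = 3
    inflation: float = 1.5
    n_random: int = 60
    crossfeed_metabolites: tuple = ("aa_arg", "vitb1", "rib")


@dataclass
class WorldReport:
    genome_ids: list
    community_plans: list
    crossfeed_plans: list
    graph: object
    predicted_communities: list
    singletons: set
    rand_index: float
    planted_smetana: dict
    typing: list
    thresholds: communities.NullThresholds
    records_by_community: dict


def _planted_partition(genomes: Sequence[str], plans) -> dict[str, int]:
    labels = {}
    for k, plan in enumerate(plans):
        for g in plan.member_genomes:
            labels[g] = k
    nxt = len(plans)
    for g in genomes:
        if g not in labels:
            labels[g] = nxt
            nxt += 1
    return labels


def run_world(seed: int, cfg: WorldConfig = WorldConfig()) -> WorldReport:
    """Run the full pipeline on a seeded synthetic world."""
    rng = np.random.default_rng(seed)
    n_members = cfg.n_communities * cfg.community_size
    n_genomes = n_members + cfg.n_background
    gids = [f"g{i:04d}" for i in range(n_genomes)]
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]

    # planted co-active communities on the activity layer
    # Each community is a tightly coupled core pair (the future donor and
    # receiver, high loadings) plus looser associates (low loadings): the
    # core edge then survives conditioning on the weakly loaded members,
    # which are poor proxies of the latent factor.
    plans = []
    for k in range(cfg.n_communities):
        members = gids[k * cfg.community_size : (k + 1) * cfg.community_size]
        support = rng.choice(samples, cfg.support_size, replace=False)
        loadings = {
            g: float(rng.uniform(1.25, 1.35) if i < 2 else rng.uniform(0.65, 0.75))
            for i, g in enumerate(members)
        }
        plans.append(
            synthetic.CommunityPlan(
                f"comm{k}", frozenset(members), loadings, frozenset(support)
            )
        )

    genomes_meta, annotations = synthetic.gen_genome_table(
        n_genomes,
        [synthetic.ScalingLawSpec(f"cat{i:02d}", 0.05 + 0.01 * i, 1.0, 0.15) for i in range(12)],
        seed=int(rng.integers(2**31)),
    )
    cov_mg, cov_mt, truth = synthetic.gen_omics_profiles(
        gids, plans, cfg.n_samples, noise=cfg.noise, seed=int(rng.integers(2**31))
    )
    lengths = genomes_meta["genome_length"].to_dict()
    _, activity_m = profiling.build_matrices(cov_mg, cov_mt, genome_lengths=lengths)
    clr = profiling.clr_transform(activity_m)

    graph = network.infer_network(
        clr, network.NetworkConfig(alpha=cfg.alpha, max_k=cfg.max_k)
    )
    predicted, singletons = mcl.mcl_cluster(graph, mcl.MCLConfig(inflation=cfg.inflation))

    # planted-vs-recovered partition agreement over all network genomes
    nodes = sorted(graph.nodes())
    truth_labels = _planted_partition(nodes, plans)
    pred_labels = {}
    for k, comm in enumerate(predicted):
        for g in comm:
            pred_labels[g] = k
    nxt = len(predicted)
    for g in nodes:
        if g not in pred_labels:
            pred_labels[g] = nxt
            nxt += 1
    ri = float(
        rand_score([truth_labels[g] for g in nodes], [pred_labels[g] for g in nodes])
    )

    # toy metabolic models with one planted obligate cross-feeding per community
    xplans = []
    for k, plan in enumerate(plans):
        members = sorted(plan.member_genomes)
        met = cfg.crossfeed_metabolites[k % len(cfg.crossfeed_metabolites)]
        xplans.append(synthetic.CrossFeedPlan(members[0], members[1], met))
    models = synthetic.gen_toy_models(gids, xplans, seed=seed)

    def score_community(members: Sequence[str]):
        mods = [models[g] for g in sorted(members)]
        recs = metabolism.detailed_scores(mods)
        _, norm = metabolism.community_scores(recs, len(mods))
        return recs, norm

    records_by_community: dict[str, list] = {}
    norm_scores: dict[str, float] = {}
    for k, comm in enumerate(predicted):
        cid = f"pred{k}"
        if 2 <= len(comm) <= 6:
            recs, norm = score_community(comm)
        else:  # pathological merge; skip exact scoring
            recs, norm = [], 0.0
        records_by_community[cid] = recs
        norm_scores[cid] = norm

    planted_smetana = {}
    for xp in xplans:
        found = 0.0
        for recs in records_by_community.values():
            for r in recs:
                if (r.donor, r.receiver, r.metabolite.rsplit("_", 1)[0]) == (
                    xp.donor,
                    xp.receiver,
                    xp.metabolite,
                ):
                    found = max(found, r.smetana)
        planted_smetana[(xp.donor, xp.receiver, xp.metabolite)] = found

    # phylogeny over all genomes, joined across domains
    domains = genomes_meta["domain"].to_dict()
    if len(set(domains.values())) == 1:  # force both domains to exist
        domains[gids[-1]] = "Archaea" if list(domains.values())[0] == "Bacteria" else "Bacteria"
    trees = synthetic.gen_phylogeny(gids, domains, seed=int(rng.integers(2**31)))
    joined = catalog.join_domain_trees(trees["Bacteria"], trees["Archaea"])
    dm = catalog.tip_distance_matrix(joined)

    # null model: random communities from the network pool
    pool = nodes
    sizes = [len(c) for c in predicted] or [cfg.community_size]
    random_comms = communities.sample_random_communities(
        pool, sizes, max(cfg.n_random, 30), seed=int(rng.integers(2**31))
    )
    null_pds, null_scores = [], []
    for comm in random_comms:
        null_pds.append(catalog.mean_community_pd(dm, comm))
        recs, norm = score_community(comm)
        null_scores.append(norm)
    thresholds = communities.compute_null_thresholds(null_pds, null_scores)

    ko_sets = {
        g: set(annotations.columns[annotations.loc[g] > 0]) for g in gids
    }
    typing = []
    for k, comm in enumerate(predicted):
        cid = f"pred{k}"
        mean_pd = catalog.mean_community_pd(dm, comm)
        gini = communities.functional_gini(
            communities.functional_capitals(comm, ko_sets)
        )
        typing.append(
            communities.TypingResult(
                cid,
                mean_pd,
                norm_scores[cid],
                gini,
                communities.classify_community(mean_pd, norm_scores[cid], thresholds),
            )
        )

    return WorldReport(
        genome_ids=gids,
        community_plans=plans,
        crossfeed_plans=xplans,
        graph=graph,
        predicted_communities=predicted,
        singletons=singletons,
        rand_index=ri,
        planted_smetana=planted_smetana,
        typing=typing,
        thresholds=thresholds,
        records_by_community=records_by_community,
    )


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------


def filter_fidelity(seed: int, n_records: int = 10_000) -> float:
    """Agreement between the alignment filter and planted pass/fail labels."""
    table = synthetic.gen_alignment_records(n_records, seed=seed)
    records = [
        profiling.AlignmentRecord(
            row.read_id, row.genome_id, int(row.L), int(row.NM), int(row.XN),
            int(row.MAPQ), row.sample_id, int(row.start), int(row.end),
        )
        for row in table.itertuples()
    ]
    kept, _ = profiling.filter_alignments(records)
    kept_ids = {r.read_id for r in kept}
    agree = sum(
        (row.read_id in kept_ids) == bool(row.truth_pass) for row in table.itertuples()
    )
    return agree / n_records


def scaling_slope_recovery(
    seed: int, n_genomes: int = 500, beta: float = 1.25, sigma: float = 0.1
) -> float:
    """Fitted scaling slope on a noisy synthetic category (truth beta)."""
    spec = synthetic.ScalingLawSpec("cat", c=0.1, beta=beta, sigma=sigma)
    genomes, annotations = synthetic.gen_genome_table(n_genomes, [spec], seed=seed)
    fit = scaling.fit_scaling_law(
        genomes["n_cds"].values, annotations["cat"].values, "cat"
    )
    return fit.slope


def enrichment_scan_experiment(
    seed: int,
    n_seeds: int = 50,
    shift: float = 0.30,
    n_categories: int = 20,
    n_genomes: int = 500,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Planted-shift detection rate and null false-positive rate.

    Returns (hit_rate, null_fpr): the fraction of seeds where the single
    shifted category is the only BH-significant one at ``alpha``, and the
    fraction of raw p-values below ``alpha`` across matched no-shift
    scans.
    """
    rng = np.random.default_rng(seed)
    specs = [
        synthetic.ScalingLawSpec(f"cat{i:02d}", c=0.05 + 0.005 * i, beta=1.0 + 0.02 * i, sigma=0.1)
        for i in range(n_categories)
    ]
    target = "cat07"
    hits = 0
    null_sig = 0
    null_total = 0
    for _ in range(n_seeds):
        sub_seed = int(rng.integers(2**31))
        gids = [f"g{i:04d}" for i in range(n_genomes)]
        group_a = gids[: n_genomes // 2]
        genomes, annotations = synthetic.gen_genome_table(
            n_genomes, specs, group_shifts={target: shift}, group_ids=group_a,
            seed=sub_seed,
        )
        table = scaling.enrichment_scan(
            annotations, group_a, gids[n_genomes // 2 :], totals=genomes["n_cds"]
        )
        sig = table.index[(table["tested"]) & (table["p_bh"] <= alpha)]
        if list(sig) == [target]:
            hits += 1
        # matched null scan: no shift
        _, annotations0 = synthetic.gen_genome_table(n_genomes, specs, seed=sub_seed + 1)
        table0 = scaling.enrichment_scan(
            annotations0, group_a, gids[n_genomes // 2 :]
        )
        tested0 = table0[table0["tested"]]
        null_sig += int((tested0["p_value"] < alpha).sum())
        null_total += len(tested0)
    return hits / n_seeds, null_sig / null_total


def chain_recovery_rate(
    seed: int, n_seeds: int = 100, n_obs: int = 500, alpha: float = 0.01
) -> float:
    """Fraction of seeds where X->Y->Z yields exactly edges X-Y and Y-Z."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_seeds):
        r = np.random.default_rng(int(rng.integers(2**31)))
        x = r.normal(size=n_obs)
        y = x + r.normal(scale=0.8, size=n_obs)
        z = y + r.normal(scale=0.8, size=n_obs)
        mat = pd.DataFrame(
            np.vstack([x, y, z]), index=["X", "Y", "Z"],
            columns=[f"s{i}" for i in range(n_obs)],
        )
        g = network.infer_network(mat, network.NetworkConfig(alpha=alpha))
        edges = {frozenset(e) for e in g.edges()}
        if edges == {frozenset({"X", "Y"}), frozenset({"Y", "Z"})}:
            ok += 1
    return ok / n_seeds


def noise_edge_mean(
    seed: int, n_seeds: int = 100, n_vars: int = 20, n_obs: int = 100,
    alpha: float = 0.01,
) -> float:
    """Mean edge count on independent Gaussian noise (type-I calibration)."""
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_seeds):
        r = np.random.default_rng(int(rng.integers(2**31)))
        mat = pd.DataFrame(
            r.normal(size=(n_vars, n_obs)),
            index=[f"v{i:02d}" for i in range(n_vars)],
            columns=[f"s{i}" for i in range(n_obs)],
        )
        g = network.infer_network(mat, network.NetworkConfig(alpha=alpha))
        counts.append(g.number_of_edges())
    return float(np.mean(counts))
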