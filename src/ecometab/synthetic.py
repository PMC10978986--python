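"""Synthetic data generation for the whole pipeline.

Every input the analysis consumes can be generated here at desk scale,
with the statistical structure the downstream methods assume, together
with the planted ground truth needed for recovery tests:

* genome metadata and per-category gene counts following power laws of
  genome size with multiplicative (log10-normal) noise, optionally with
  planted per-category log10 offsets for a genome subgroup;
* random bifurcating phylogenies per domain;
* paired metagenomic/metatranscriptomic coverage tables in which planted
  communities co-vary on the *activity* layer through a shared lognormal
  latent factor, with compositional closure per sample;
* alignment summary records with consistent NM/XN/L fields and ground
  truth pass/fail labels for the identity/MAPQ filter;
* toy stoichiometric models with planted obligate cross-feedings
  (receiver auxotrophic for a metabolite only the donor can secrete);
* symmetric ANI/coverage matrices with a planted species partition.

All generators are deterministic functions of their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metabolism import FLUX_MAX, MetabolicModel, Metabolite, Reaction

__all__ = [
    "ScalingLawSpec",
    "CommunityPlan",
    "CrossFeedPlan",
    "gen_genome_table",
    "gen_phylogeny",
    "gen_omics_profiles",
    "gen_alignment_records",
    "gen_toy_models",
    "gen_ani_matrix",
    "CROSSFEED_UNIVERSE",
]


@dataclass(frozen=True)
class ScalingLawSpec:
    """Power law y = c * x**beta with log10-normal multiplicative noise."""

    category_id: str
    c: float
    beta: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"{self.category_id}: prefactor c must be > 0")
        if self.sigma < 0:
            raise ValueError(f"{self.category_id}: sigma must be >= 0")


@dataclass(frozen=True)
class CommunityPlan:
    """A planted co-active community driving the activity layer."""

    community_id: str
    member_genomes: frozenset
    latent_factor_loadings: Mapping[str, float]
    sample_support: frozenset

    def __post_init__(self) -> None:
        if len(self.member_genomes) < 2:
            raise ValueError("community needs >= 2 members")
        if set(self.latent_factor_loadings) != set(self.member_genomes):
            raise ValueError("loadings must cover exactly the members")
        if any(l <= 0 for l in self.latent_factor_loadings.values()):
            raise ValueError("loadings must be positive")


@dataclass(frozen=True)
class CrossFeedPlan:
    """Planted cross-feeding: donor secretes a metabolite the receiver needs."""

    donor: str
    receiver: str
    metabolite: str
    obligate: bool = True

    def __post_init__(self) -> None:
        if self.donor == self.receiver:
            raise ValueError("donor and receiver must differ")


def _round_half_up(v: np.ndarray) -> np.ndarray:
    return np.floor(v + 0.5)


def gen_genome_table(
    n_genomes: int,
    specs: Sequence[ScalingLawSpec],
    group_shifts: Mapping[str, float] | None = None,
    group_ids: Iterable[str] | None = None,
    seed: int = 0,
    log10_total_range: tuple[float, float] = (3.0, 4.2),
    completeness_range: tuple[float, float] = (0.75, 1.0),
    contamination_range: tuple[float, float] = (0.0, 0.05),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome metadata plus per-category annotation counts.

    Total gene counts are drawn log-uniformly over at least one order of
    magnitude; for each category, log10(count) = log10(c) +
    beta * log10(total) + Normal(0, sigma), plus the configured per-category
    offset for genomes in ``group_ids``; counts are rounded half-up to
    non-negative integers.

    Returns ``(genomes, annotations)``: a metadata table and a wide
    genomes x categories count table.
    """
    if n_genomes < 2:
        raise ValueError("need >= 2 genomes")
    if not specs:
        raise ValueError("empty spec list")
    if log10_total_range[1] - log10_total_range[0] < 1.0:
        raise ValueError("total gene counts must span >= 1 order of magnitude")
    rng = np.random.default_rng(seed)
    gids = [f"g{i:04d}" for i in range(n_genomes)]
    group = set(group_ids or [])
    shifts = dict(group_shifts or {})

    log_x = rng.uniform(*log10_total_range, n_genomes)
    x = _round_half_up(10**log_x).astype(int)
    counts = {}
    for spec in specs:
        mu = np.log10(spec.c) + spec.beta * np.log10(x)
        noise = rng.normal(0.0, spec.sigma, n_genomes) if spec.sigma > 0 else 0.0
        shift = np.array(
            [shifts.get(spec.category_id, 0.0) if g in group else 0.0 for g in gids]
        )
        y = _round_half_up(10 ** (mu + noise + shift))
        counts[spec.category_id] = np.maximum(y, 0).astype(int)
    annotations = pd.DataFrame(counts, index=pd.Index(gids, name="genome_id"))

    completeness = rng.uniform(*completeness_range, n_genomes)
    contamination = rng.uniform(*contamination_range, n_genomes)
    genomes = pd.DataFrame(
        {
            "genome_id": gids,
            "completeness": completeness,
            "contamination": contamination,
            "genome_length": (x * rng.uniform(900, 1100, n_genomes)).astype(int),
            "n_cds": x,
            "domain": rng.choice(["Bacteria", "Archaea"], n_genomes, p=[0.9, 0.1]),
            "source_class": rng.choice(["MAG", "WGS", "SAG"], n_genomes, p=[0.6, 0.3, 0.1]),
            "in_group": [g in group for g in gids],
        }
    ).set_index("genome_id")
    return genomes, annotations


def gen_phylogeny(
    genome_ids: Sequence[str],
    domain_labels: Mapping[str, str],
    seed: int = 0,
    mean_branch: float = 0.2,
) -> dict[str, str]:
    """Random bifurcating Newick trees, one per domain.

    Built by random sequential joining with exponential branch lengths;
    byte-identical output under the same seed. Every genome must carry
    exactly one domain label.
    """
    if len(set(genome_ids)) != len(genome_ids):
        raise ValueError("duplicate leaf names")
    missing = [g for g in genome_ids if g not in domain_labels]
    if missing:
        raise ValueError(f"genomes without domain label: {missing}")
    rng = np.random.default_rng(seed)
    trees: dict[str, str] = {}
    for domain in sorted(set(domain_labels[g] for g in genome_ids)):
        leaves = [g for g in genome_ids if domain_labels[g] == domain]
        subtrees = [f"{g}:{rng.exponential(mean_branch):.6f}" for g in leaves]
        while len(subtrees) > 1:
            i, j = sorted(rng.choice(len(subtrees), 2, replace=False))
            b = subtrees.pop(j)
            a = subtrees.pop(i)
            length = rng.exponential(mean_branch)
            subtrees.append(f"({a},{b}):{length:.6f}")
        trees[domain] = subtrees[0].rsplit(":", 1)[0] + ";" if len(leaves) > 1 else f"({subtrees[0]});"
    return trees


def gen_omics_profiles(
    genome_ids: Sequence[str],
    plans: Sequence[CommunityPlan],
    n_samples: int,
    noise: float = 0.25,
    seed: int = 0,
    depth_total: float = 1e4,
    background_activity_sd: float = 0.6,
    background_absence_rate: float = 0.2,
    force_breadth: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired metagenomic/metatranscriptomic coverage tables.

    Within a plan's sample support, member activities co-vary through a
    shared lognormal latent factor scaled by the member loadings, with
    residual log-noise of standard deviation ``noise``. Outside supports
    (and for non-member genomes) activities are independent lognormal
    background. Metagenomic depths are only weakly structured. Breadths
    guarantee that planted members pass the 30% detection rule in their
    support samples, while background genomes drop below it at the
    configured absence rate. Depths are closed per sample to
    ``depth_total``.

    Returns ``(coverage_metaG, coverage_metaT, truth)`` where the truth
    dict carries the plans and an ``overlapping_members`` flag.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    genome_ids = list(genome_ids)
    members_seen: set[str] = set()
    overlap = False
    for plan in plans:
        unknown = plan.member_genomes - set(genome_ids)
        if unknown:
            raise ValueError(f"plan {plan.community_id} references unknown genomes {sorted(unknown)}")
        if plan.sample_support - set(samples):
            raise ValueError(f"plan {plan.community_id} references unknown samples")
        if plan.member_genomes & members_seen:
            overlap = True
        members_seen |= plan.member_genomes

    n_g = len(genome_ids)
    mu_g = rng.normal(1.0, 0.4, n_g)
    depth_mg = np.exp(mu_g[:, None] + rng.normal(0.0, 0.3, (n_g, n_samples)))

    log_act = rng.normal(0.0, background_activity_sd, (n_g, n_samples))
    factors = {p.community_id: rng.normal(0.0, 1.0, n_samples) for p in plans}
    gpos = {g: i for i, g in enumerate(genome_ids)}
    spos = {s: j for j, s in enumerate(samples)}
    for plan in plans:
        f = factors[plan.community_id]
        for g in sorted(plan.member_genomes):
            load = plan.latent_factor_loadings[g]
            for s in plan.sample_support:
                log_act[gpos[g], spos[s]] = load * f[spos[s]] + rng.normal(0.0, noise)
    depth_mt = depth_mg * np.exp(log_act)

    breadth = rng.uniform(0.4, 0.95, (n_g, n_samples))
    absent = rng.random((n_g, n_samples)) < background_absence_rate
    breadth[absent] = rng.uniform(0.05, 0.25, int(absent.sum()))
    for plan in plans:
        for g in sorted(plan.member_genomes):
            for s in plan.sample_support:
                breadth[gpos[g], spos[s]] = max(breadth[gpos[g], spos[s]], 0.5)
    if force_breadth:
        for g, b in force_breadth.items():
            breadth[gpos[g], :] = b

    # compositional closure: per-sample depth totals equal depth_total
    depth_mg = depth_mg / depth_mg.sum(axis=0) * depth_total
    depth_mt = depth_mt / depth_mt.sum(axis=0) * depth_total

    def long(depths: np.ndarray) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(genome_ids):
            for j, s in enumerate(samples):
                rows.append((g, s, depths[i, j], breadth[i, j]))
        return pd.DataFrame(rows, columns=["genome_id", "sample_id", "depth", "breadth"])

    truth = {
        "plans": list(plans),
        "overlapping_members": overlap,
        "samples": samples,
    }
    return long(depth_mg), long(depth_mt), truth


def gen_alignment_records(
    n_records: int,
    length_range: tuple[int, int] = (80, 150),
    identity_range: tuple[float, float] = (0.85, 1.0),
    mapq_range: tuple[int, int] = (0, 60),
    ambiguous_base_rate: float = 0.02,
    seed: int = 0,
    genome_ids: Sequence[str] = ("g0000",),
    sample_ids: Sequence[str] = ("S000",),
    genome_length: int = 100_000,
    min_mapq: int = 20,
    min_identity: float = 0.95,
) -> pd.DataFrame:
    """Alignment summary records with ground-truth filter labels.

    Fields satisfy 0 <= XN <= NM <= L by construction; the ``truth_pass``
    column applies the MAPQ/identity rule (identity = 1 - (NM - XN)/L)
    at generation time so filter fidelity can be asserted exactly.
    """
    if not (length_range[0] <= length_range[1] and 0 <= identity_range[0] <= identity_range[1] <= 1):
        raise ValueError("invalid ranges")
    rng = np.random.default_rng(seed)
    L = rng.integers(length_range[0], length_range[1] + 1, n_records)
    identity = rng.uniform(*identity_range, n_records)
    XN = rng.binomial(L, ambiguous_base_rate)
    NM = np.minimum(_round_half_up((1.0 - identity) * L).astype(int) + XN, L)
    XN = np.minimum(XN, NM)
    mapq = rng.integers(mapq_range[0], mapq_range[1] + 1, n_records)
    start = rng.integers(0, np.maximum(genome_length - L, 1))
    realized_identity = 1.0 - (NM - XN) / L
    df = pd.DataFrame(
        {
            "read_id": [f"r{i:06d}" for i in range(n_records)],
            "genome_id": rng.choice(list(genome_ids), n_records),
            "sample_id": rng.choice(list(sample_ids), n_records),
            "L": L,
            "NM": NM,
            "XN": XN,
            "MAPQ": mapq,
            "start": start,
            "end": start + L,
            "truth_pass": (mapq >= min_mapq) & (realized_identity >= min_identity),
        }
    )
    return df


# -- toy metabolic models ---------------------------------------------------

#: Organic metabolites available for planted cross-feedings (base names),
#: with approximate molecular weights (g/mol).
CROSSFEED_UNIVERSE = {
    "glc": 180.2,   # D-glucose, the shared carbon source
    "aa_arg": 174.2,
    "aa_glu": 147.1,
    "aa_met": 149.2,
    "vitb1": 265.4,  # thiamine
    "vitb12": 1355.4,
    "rib": 150.1,    # D-ribose
    "orn": 132.2,
    "ac": 60.1,      # acetate
    "etoh": 46.1,
}

_INORGANICS = {"pi": 95.0, "nh4": 18.0, "h2o": 18.0}


def _toy_model(
    genome_id: str,
    secretes: Sequence[str],
    requires: Sequence[str],
    facultative: Sequence[str] = (),
) -> MetabolicModel:
    """One toy genome-scale model over the shared metabolite universe.

    ``secretes``: metabolites the genome can synthesize from glucose and
    export. ``requires``: metabolites its biomass needs but it cannot
    synthesize (auxotrophies, must import). ``facultative``: required by
    biomass but synthesizable as well (importer also present).
    """
    mets: dict[str, Metabolite] = {}
    rxns: dict[str, Reaction] = {}

    def met(base: str, comp: str) -> str:
        mid = f"{base}_{comp}"
        if mid not in mets:
            inorganic = base in _INORGANICS
            mw = _INORGANICS.get(base, CROSSFEED_UNIVERSE.get(base))
            mets[mid] = Metabolite(mid, base, comp, inorganic, mw)
        return mid

    # core: glucose uptake + inorganics + biomass precursor
    for base in ("glc", "pi", "nh4"):
        e, c = met(base, "e"), met(base, "c")
        rxns[f"EX_{e}"] = Reaction(f"EX_{e}", {e: -1.0})
        mech = "ABC" if base == "glc" else "uniport"
        rxns[f"T_{base}"] = Reaction(
            f"T_{base}", {e: -1.0, c: 1.0}, gene_rule=f"{genome_id}_t_{base}",
            transport={"mechanism": mech, "direction": "import"},
        )
    prec = met("prec", "c")
    rxns["SYN_prec"] = Reaction(
        "SYN_prec", {met("glc", "c"): -1.0, met("nh4", "c"): -1.0, met("pi", "c"): -0.2, prec: 1.0},
        gene_rule=f"{genome_id}_syn_prec",
    )
    biomass_stoich = {prec: -1.0}

    for base in secretes:
        if base not in CROSSFEED_UNIVERSE:
            raise ValueError(f"metabolite {base!r} not in the toy universe")
        e, c = met(base, "e"), met(base, "c")
        rxns[f"SYN_{base}"] = Reaction(
            f"SYN_{base}", {met("glc", "c"): -1.0, c: 1.0},
            gene_rule=f"{genome_id}_syn_{base}",
        )
        rxns[f"T_{base}_out"] = Reaction(
            f"T_{base}_out", {c: -1.0, e: 1.0}, gene_rule=f"{genome_id}_t_{base}_out",
            transport={"mechanism": "diffusion", "direction": "export"},
        )
        rxns[f"EX_{e}"] = Reaction(f"EX_{e}", {e: -1.0})

    for base in list(requires) + list(facultative):
        if base not in CROSSFEED_UNIVERSE:
            raise ValueError(f"metabolite {base!r} not in the toy universe")
        e, c = met(base, "e"), met(base, "c")
        rxns[f"T_{base}_in"] = Reaction(
            f"T_{base}_in", {e: -1.0, c: 1.0}, gene_rule=f"{genome_id}_t_{base}_in",
            transport={"mechanism": "ABC", "direction": "import"},
        )
        rxns.setdefault(f"EX_{e}", Reaction(f"EX_{e}", {e: -1.0}))
        biomass_stoich[c] = -0.5
        if base in facultative:
            rxns[f"SYN_{base}"] = Reaction(
                f"SYN_{base}", {met("glc", "c"): -1.0, c: 1.0},
                gene_rule=f"{genome_id}_syn_{base}",
            )

    rxns["BIOMASS"] = Reaction("BIOMASS", biomass_stoich, 0.0, FLUX_MAX,
                               gene_rule=None)
    return MetabolicModel(genome_id, mets, rxns, "BIOMASS")


def gen_toy_models(
    genome_ids: Sequence[str],
    plans: Sequence[CrossFeedPlan] = (),
    seed: int = 0,
) -> dict[str, MetabolicModel]:
    """Toy stoichiometric models with planted cross-feedings.

    Every genome is a glucose prototroph; for each obligate plan the
    receiver's biomass additionally requires the planted metabolite,
    which it cannot synthesize, while the donor gains a synthesis and
    secretion route for it. Non-obligate plans give the receiver both the
    importer and its own synthesis route. Genomes in no plan are
    prototroph controls.
    """
    known = set(genome_ids)
    secretes: dict[str, set[str]] = {g: set() for g in genome_ids}
    requires: dict[str, set[str]] = {g: set() for g in genome_ids}
    facult: dict[str, set[str]] = {g: set() for g in genome_ids}
    for plan in plans:
        if plan.donor not in known or plan.receiver not in known:
            raise ValueError(f"plan references unknown genome: {plan}")
        if plan.metabolite not in CROSSFEED_UNIVERSE:
            raise ValueError(f"metabolite {plan.metabolite!r} not in the toy universe")
        secretes[plan.donor].add(plan.metabolite)
        if plan.obligate:
            requires[plan.receiver].add(plan.metabolite)
        else:
            facult[plan.receiver].add(plan.metabolite)
    return {
        g: _toy_model(g, sorted(secretes[g]), sorted(requires[g]), sorted(facult[g]))
        for g in genome_ids
    }


def gen_ani_matrix(
    genome_ids: Sequence[str],
    cluster_plan: Sequence[Iterable[str]],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric ANI and alignment-coverage matrices with a planted partition.

    Within-cluster pairs get ANI >= 0.95 and coverage >= 0.60;
    between-cluster pairs get ANI <= 0.90.
    """
    parts = [sorted(set(p)) for p in cluster_plan]
    flat = [g for p in parts for g in p]
    if sorted(flat) != sorted(genome_ids) or len(flat) != len(set(flat)):
        raise ValueError("cluster plan must partition the genome ids")
    rng = np.random.default_rng(seed)
    ids = list(genome_ids)
    n = len(ids)
    label = {g: k for k, p in enumerate(parts) for g in p}
    ani = np.zeros((n, n))
    cov = np.zeros((n, n))
    for i in range(n):
        ani[i, i] = 1.0
        cov[i, i] = 1.0
        for j in range(i + 1, n):
            same = label[ids[i]] == label[ids[j]]
            a = rng.uniform(0.96, 0.995) if same else rng.uniform(0.75, 0.88)
            c = rng.uniform(0.7, 0.95) if same else rng.uniform(0.3, 0.9)
            ani[i, j] = ani[j, i] = a
            cov[i, j] = cov[j, i] = c
    return (
        pd.DataFrame(ani, index=ids, columns=ids),
        pd.DataFrame(cov, index=ids, columns=ids),
    )
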