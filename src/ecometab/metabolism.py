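"""Constraint-based community metabolic modelling and cross-feeding scores.

Implements flux-balance growth checks, exhaustive minimal-medium
enumeration, and the community interaction scores used to rank putative
cross-feeding interactions between genomes:

* **MRO** (metabolic resource overlap): how much community members
  compete for the same external metabolites, computed from the unions of
  their minimal nutritional requirements.
* **MIP** (metabolic interaction potential): how many external
  metabolites the community can spare by exchanging metabolites, i.e.
  the size difference between the smallest community medium when members
  are metabolically isolated (private extracellular pools) versus when
  they share a common pool.
* **SCS / MUS / MPS** and their product, the pairwise cross-feeding
  (smetana) score for a (donor, receiver, metabolite) hypothesis:
  coupling of the receiver's survival to the donor, frequency of the
  metabolite among the receiver's minimal uptake requirements, and the
  donor's ability to secrete the metabolite.

All enumerations are exact (lattice search with superset pruning) and
are intended for small models (tens of reactions) and communities of at
most ~6 members; growth is decided by linear programming (HiGHS via
scipy) with a configurable minimum biomass flux ``g_min``.

Metabolite ids end in an underscore-separated compartment tag
(e.g. ``glc_e`` extracellular, ``glc_c`` cytosolic). Exchange reactions
are named ``EX_<metabolite>`` and touch exactly one extracellular
metabolite with coefficient -1; negative flux is uptake. Inorganic
compounds (water, phosphate, ammonium, iron cations, ...) are freely
available in every medium and excluded from all cross-feeding records.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "CommunityModel",
    "GrowthResult",
    "PairwiseScore",
    "build_community",
    "check_growth",
    "check_community_growth",
    "minimal_media",
    "minimal_medium",
    "smallest_community_medium",
    "mro",
    "mip",
    "detailed_scores",
    "community_scores",
    "classify_transporters",
    "transporter_activity",
    "categorize_metabolites",
    "TRANSPORTER_MECHANISMS",
]

G_MIN = 1e-4
UPTAKE_MAX = 10.0
FLUX_MAX = 1000.0
SECRETION_TOL = 1e-6
SCHEMA = "ecometab-model-1"

#: The nine transporter mechanism classes (plus the "other" fallback).
TRANSPORTER_MECHANISMS = (
    "ABC",
    "proton symport",
    "proton antiport",
    "sodium symport",
    "uniport",
    "diffusion",
    "PTS",
    "vectorial group translocation",
    "other",
)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_inorganic: bool = False
    mw: float | None = None  # g/mol, optional


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float = 0.0
    ub: float = FLUX_MAX
    gene_rule: str | None = None
    transport: dict | None = None  # {"mechanism": ..., "direction": ...}

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lb > ub")

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub

    @property
    def genes(self) -> list[str]:
        if not self.gene_rule:
            return []
        return sorted(set(re.findall(r"[A-Za-z0-9_.\-]+", self.gene_rule)) - {"and", "or", "AND", "OR"})


@dataclass
class MetabolicModel:
    """A small stoichiometric model with exchange and biomass reactions."""

    model_id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_reaction_id: str

    def __post_init__(self) -> None:
        if self.biomass_reaction_id not in self.reactions:
            raise ValueError(f"{self.model_id}: biomass reaction missing")
        for rxn in self.reactions.values():
            for met in rxn.stoich:
                if met not in self.metabolites:
                    raise ValueError(f"{self.model_id}: unknown metabolite {met} in {rxn.id}")
            if rxn.id.startswith("EX_"):
                if len(rxn.stoich) != 1:
                    raise ValueError(f"exchange {rxn.id} must touch exactly one metabolite")
                (met,) = rxn.stoich
                if self.metabolites[met].compartment != "e":
                    raise ValueError(f"exchange {rxn.id} must touch an extracellular metabolite")

    # -- convenience views ------------------------------------------------
    def exchange_reactions(self) -> dict[str, Reaction]:
        return {rid: r for rid, r in self.reactions.items() if rid.startswith("EX_")}

    def extracellular(self, organic_only: bool = False) -> list[str]:
        mets = [
            m.id
            for m in self.metabolites.values()
            if m.compartment == "e" and not (organic_only and m.is_inorganic)
        ]
        return sorted(mets)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "schema": SCHEMA,
            "model_id": self.model_id,
            "biomass_reaction_id": self.biomass_reaction_id,
            "metabolites": [asdict(m) for m in self.metabolites.values()],
            "reactions": [asdict(r) for r in self.reactions.values()],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MetabolicModel":
        payload = json.loads(text)
        if payload.get("schema") != SCHEMA:
            raise ValueError(f"unsupported model schema: {payload.get('schema')!r}")
        mets = {m["id"]: Metabolite(**m) for m in payload["metabolites"]}
        rxns = {r["id"]: Reaction(**r) for r in payload["reactions"]}
        return cls(payload["model_id"], mets, rxns, payload["biomass_reaction_id"])


def read_sbml(path: str, model_id: str | None = None) -> MetabolicModel:
    """Optional SBML-FBC import, mapped onto the JSON schema (needs cobra)."""
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML import requires the optional cobra dependency") from exc
    cm = cobra.io.read_sbml_model(path)
    mets = {
        m.id: Metabolite(m.id, m.name or "", m.compartment or "c", False,
                         m.formula_weight or None)
        for m in cm.metabolites
    }
    rxns = {}
    for r in cm.reactions:
        rxns[r.id] = Reaction(
            r.id,
            {m.id: float(coef) for m, coef in r.metabolites.items()},
            float(r.lower_bound),
            float(r.upper_bound),
            r.gene_reaction_rule or None,
        )
    biomass = cm.objective.expression
    biomass_ids = [r.id for r in cm.reactions if r.objective_coefficient]
    if not biomass_ids:
        raise ValueError("SBML model has no objective (biomass) reaction")
    return MetabolicModel(model_id or cm.id or "model", mets, rxns, biomass_ids[0])


@dataclass(frozen=True)
class GrowthResult:
    grows: bool
    objective: float
    status: str  # optimal / infeasible


@dataclass(frozen=True)
class PairwiseScore:
    donor: str
    receiver: str
    metabolite: str
    scs: float
    mus: float
    mps: float

    @property
    def smetana(self) -> float:
        return self.scs * self.mus * self.mps


class SolverFailure(RuntimeError):
    """LP solver failed for a reason other than plain infeasibility."""


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------


def _fba(
    model: MetabolicModel,
    medium: Iterable[str],
    objective: Mapping[str, float],
    extra_lb: Mapping[str, float] | None = None,
    maximize: bool = True,
) -> tuple[float | None, dict[str, float] | None]:
    """Solve max/min of a linear flux objective s.t. S v = 0 and bounds.

    ``medium`` lists extracellular metabolite ids whose exchange uptake is
    opened (lb = -UPTAKE_MAX); inorganic metabolites are always open.
    Returns (objective value, flux dict) or (None, None) when infeasible.
    """
    met_ids = sorted(model.metabolites)
    rxn_ids = sorted(model.reactions)
    met_pos = {m: i for i, m in enumerate(met_ids)}
    medium = set(medium)

    S = np.zeros((len(met_ids), len(rxn_ids)))
    bounds = []
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        for met, coef in rxn.stoich.items():
            S[met_pos[met], j] = coef
        lb, ub = rxn.lb, rxn.ub
        if rid.startswith("EX_"):
            (met,) = rxn.stoich
            open_uptake = met in medium or model.metabolites[met].is_inorganic
            lb = -UPTAKE_MAX if open_uptake else 0.0
            ub = FLUX_MAX
        if extra_lb and rid in extra_lb:
            lb = max(lb, extra_lb[rid])
        bounds.append((lb, ub))

    c = np.zeros(len(rxn_ids))
    for rid, coef in objective.items():
        c[rxn_ids.index(rid)] = coef
    sign = -1.0 if maximize else 1.0
    res = linprog(sign * c, A_eq=S, b_eq=np.zeros(len(met_ids)), bounds=bounds,
                  method="highs")
    if res.status == 2:  # infeasible
        return None, None
    if res.status != 0:
        raise SolverFailure(f"linprog status {res.status}: {res.message}")
    fluxes = dict(zip(rxn_ids, res.x))
    return float(-res.fun) if maximize else float(res.fun), fluxes


def check_growth(
    model: MetabolicModel, medium: Iterable[str], g_min: float = G_MIN
) -> GrowthResult:
    """Maximize biomass flux on a medium; grows iff optimum >= g_min."""
    value, _ = _fba(model, medium, {model.biomass_reaction_id: 1.0})
    if value is None:
        return GrowthResult(False, 0.0, "infeasible")
    return GrowthResult(value >= g_min, value, "optimal")


# ---------------------------------------------------------------------------
# Community construction
# ---------------------------------------------------------------------------


@dataclass
class CommunityModel:
    """Merged member models with species-tagged compartments.

    In ``shared`` mode all members see one extracellular pool (metabolites
    can flow between species through it); in ``private`` mode each member
    keeps its own pool and no metabolite can cross between species.
    """

    model: MetabolicModel
    member_biomass: dict[str, str]
    mode: str


def build_community(models: Sequence[MetabolicModel], mode: str = "shared") -> CommunityModel:
    if mode not in ("shared", "private"):
        raise ValueError(f"unknown interaction mode: {mode}")
    if len({m.model_id for m in models}) != len(models):
        raise ValueError("duplicate model ids in community")
    mets: dict[str, Metabolite] = {}
    rxns: dict[str, Reaction] = {}
    member_biomass: dict[str, str] = {}

    def met_name(met: Metabolite, sp: str) -> str:
        if met.compartment == "e" and mode == "shared":
            return met.id
        return f"{met.id}@{sp}"

    for m in models:
        sp = m.model_id
        for met in m.metabolites.values():
            name = met_name(met, sp)
            mets.setdefault(
                name,
                Metabolite(name, met.name, met.compartment, met.is_inorganic, met.mw),
            )
        for rxn in m.reactions.values():
            if rxn.id.startswith("EX_"):
                if mode == "shared":
                    continue  # replaced by community exchanges below
                (met,) = rxn.stoich
                rid = f"EX_{met}@{sp}"
                rxns[rid] = Reaction(rid, {f"{met}@{sp}": -1.0}, rxn.lb, rxn.ub)
                continue
            rid = f"{rxn.id}@{sp}"
            stoich = {met_name(m.metabolites[met], sp): c for met, c in rxn.stoich.items()}
            rxns[rid] = Reaction(rid, stoich, rxn.lb, rxn.ub)
            if rxn.id == m.biomass_reaction_id:
                member_biomass[sp] = rid
    if mode == "shared":
        for name, met in sorted(mets.items()):
            if met.compartment == "e":
                rid = f"EX_{name}"
                rxns[rid] = Reaction(rid, {name: -1.0}, 0.0, FLUX_MAX)

    merged = MetabolicModel("community", mets, rxns, next(iter(member_biomass.values())))
    return CommunityModel(merged, member_biomass, mode)


def _community_medium_sets(com: CommunityModel, medium: Iterable[str]) -> set[str]:
    """Translate a medium over base extracellular metabolites to pool ids."""
    medium = set(medium)
    opened = set()
    for met in com.model.metabolites.values():
        if met.compartment != "e":
            continue
        base = met.id.split("@", 1)[0]
        if base in medium:
            opened.add(met.id)
    return opened


def check_community_growth(
    com: CommunityModel,
    medium: Iterable[str],
    require: Iterable[str] = (),
    maximize: str | None = None,
    g_min: float = G_MIN,
) -> GrowthResult:
    """Community FBA: maximize one member (or total) biomass on a medium.

    ``require`` lists member ids whose biomass flux is constrained to be
    at least ``g_min`` (they must be alive); ``maximize`` selects the
    member whose biomass is the LP objective (total biomass if None).
    Grows iff the optimum is >= g_min and all requirements are met.
    """
    opened = _community_medium_sets(com, medium)
    extra_lb = {com.member_biomass[sp]: g_min for sp in require}
    if maximize is None:
        objective = {rid: 1.0 for rid in com.member_biomass.values()}
    else:
        objective = {com.member_biomass[maximize]: 1.0}
    try:
        value, _ = _fba(com.model, opened, objective, extra_lb=extra_lb)
    except KeyError as exc:
        raise KeyError(f"unknown community member: {exc}") from exc
    if value is None:
        return GrowthResult(False, 0.0, "infeasible")
    return GrowthResult(value >= g_min, value, "optimal")


def members_grow(
    models: Sequence[MetabolicModel],
    medium: Iterable[str],
    mode: str,
    g_min: float = G_MIN,
) -> bool:
    """True when every member can reach g_min biomass simultaneously."""
    com = build_community(models, mode)
    opened = _community_medium_sets(com, medium)
    extra_lb = {rid: g_min for rid in com.member_biomass.values()}
    objective = {next(iter(com.member_biomass.values())): 1.0}
    value, _ = _fba(com.model, opened, objective, extra_lb=extra_lb)
    return value is not None


# ---------------------------------------------------------------------------
# Minimal media
# ---------------------------------------------------------------------------


def minimal_media(
    model: MetabolicModel,
    candidates: Sequence[str] | None = None,
    g_min: float = G_MIN,
    max_candidates: int = 20,
) -> list[frozenset]:
    """All inclusion-minimal subsets of organic candidates supporting growth.

    Exhaustive lattice search in ascending cardinality with superset
    pruning (growth is monotone in the medium, so supersets of a minimal
    medium cannot be minimal). Inorganic metabolites are always available
    and never enumerated. Returns an empty list when no candidate subset
    supports growth.
    """
    if candidates is None:
        candidates = [
            m for m in model.extracellular(organic_only=True)
            if f"EX_{m}" in model.reactions
        ]
    candidates = sorted(candidates)
    if len(candidates) > max_candidates:
        raise ValueError(
            f"{len(candidates)} candidates exceed the exact-enumeration bound "
            f"({max_candidates}); restrict the candidate list"
        )
    if not check_growth(model, candidates, g_min).grows:
        return []
    found: list[frozenset] = []
    for size in range(0, len(candidates) + 1):
        for combo in combinations(candidates, size):
            s = frozenset(combo)
            if any(mm <= s for mm in found):
                continue
            if check_growth(model, s, g_min).grows:
                found.append(s)
    return sorted(found, key=lambda s: (len(s), sorted(s)))


def _medium_weight(model: MetabolicModel, medium: frozenset) -> float:
    total = 0.0
    for m in medium:
        mw = model.metabolites[m].mw
        if mw is None:
            raise ValueError(f"metabolite {m} has no molecular weight")
        total += mw
    return total


def minimal_medium(
    model: MetabolicModel,
    candidates: Sequence[str] | None = None,
    weighting: str = "count",
    g_min: float = G_MIN,
) -> frozenset | None:
    """The best minimal medium under the chosen weighting.

    ``count`` minimizes cardinality (ties: lexicographic); ``molweight``
    minimizes the summed molecular weight of the medium instead.
    """
    media = minimal_media(model, candidates, g_min)
    if not media:
        return None
    if weighting == "count":
        return min(media, key=lambda s: (len(s), sorted(s)))
    if weighting == "molweight":
        return min(media, key=lambda s: (_medium_weight(model, s), sorted(s)))
    raise ValueError(f"unknown weighting: {weighting}")


def smallest_community_medium(
    models: Sequence[MetabolicModel],
    mode: str = "shared",
    candidates: Sequence[str] | None = None,
    g_min: float = G_MIN,
) -> frozenset | None:
    """Smallest-cardinality medium on which *all* members grow.

    Deterministic: subsets of equal size are scanned in lexicographic
    order and the first feasible one is returned.
    """
    if candidates is None:
        cand: set[str] = set()
        for m in models:
            cand |= {
                x for x in m.extracellular(organic_only=True)
                if f"EX_{x}" in m.reactions
            }
        candidates = sorted(cand)
    candidates = sorted(candidates)
    if not members_grow(models, candidates, mode, g_min):
        return None
    for size in range(0, len(candidates) + 1):
        for combo in combinations(candidates, size):
            if members_grow(models, combo, mode, g_min):
                return frozenset(combo)
    return None  # pragma: no cover


# ---------------------------------------------------------------------------
# Community-wide scores
# ---------------------------------------------------------------------------


def mro(
    models: Sequence[MetabolicModel],
    candidates: Sequence[str] | None = None,
    g_min: float = G_MIN,
) -> float:
    """Metabolic resource overlap of a community.

    ``M_i`` is the union of metabolites over species i's minimal media;
    MRO = sum over pairs of |M_i & M_j| divided by the sum of
    min(|M_i|, |M_j|). 1 means complete overlap of nutritional
    requirements (maximal competition), 0 disjoint requirements.
    Members with no feasible medium or no requirements are excluded.
    """
    needs: list[set[str]] = []
    for m in models:
        media = minimal_media(m, candidates, g_min)
        union: set[str] = set().union(*media) if media else set()
        if media and union:
            needs.append(union)
    if len(needs) < 2:
        raise ValueError("MRO needs >= 2 members with non-empty requirement sets")
    num = sum(len(a & b) for a, b in combinations(needs, 2))
    den = sum(min(len(a), len(b)) for a, b in combinations(needs, 2))
    return num / den


def mip(
    models: Sequence[MetabolicModel],
    candidates: Sequence[str] | None = None,
    g_min: float = G_MIN,
) -> int:
    """Metabolic interaction potential: external metabolites spared by sharing.

    MIP = |smallest community medium, private pools| -
          |smallest community medium, shared pool|; always >= 0 because
    sharing only relaxes the private problem.
    """
    private = smallest_community_medium(models, "private", candidates, g_min)
    shared = smallest_community_medium(models, "shared", candidates, g_min)
    if private is None or shared is None:
        raise ValueError("community infeasible in private or shared mode")
    return len(private) - len(shared)


# ---------------------------------------------------------------------------
# Detailed (pairwise) scores
# ---------------------------------------------------------------------------


def _minimal_donor_sets(
    models_by_id: Mapping[str, MetabolicModel],
    receiver: str,
    medium: frozenset,
    g_min: float,
) -> list[frozenset] | None:
    """Inclusion-minimal donor sets enabling the receiver's growth.

    Donors must themselves reach g_min biomass (a dead donor secretes
    nothing). Returns None when the receiver grows without any donor.
    """
    others = sorted(set(models_by_id) - {receiver})
    if check_growth(models_by_id[receiver], medium, g_min).grows:
        return None
    found: list[frozenset] = []
    for size in range(1, len(others) + 1):
        for combo in combinations(others, size):
            s = frozenset(combo)
            if any(mm <= s for mm in found):
                continue
            com = build_community(
                [models_by_id[receiver]] + [models_by_id[d] for d in combo], "shared"
            )
            res = check_community_growth(
                com, medium, require=combo, maximize=receiver, g_min=g_min
            )
            if res.grows:
                found.append(s)
    return found


def _can_secrete(
    model: MetabolicModel, metabolite: str, medium: frozenset, g_min: float
) -> bool:
    """Can the model secrete the metabolite at nonzero flux while growing?"""
    ex = f"EX_{metabolite}"
    if ex not in model.reactions:
        return False
    value, _ = _fba(
        model,
        medium,
        {ex: 1.0},
        extra_lb={model.biomass_reaction_id: g_min},
    )
    return value is not None and value > SECRETION_TOL


def detailed_scores(
    models: Sequence[MetabolicModel],
    medium: frozenset | None = None,
    g_min: float = G_MIN,
    exclude_inorganic: bool = True,
    max_members: int = 6,
) -> list[PairwiseScore]:
    """Pairwise cross-feeding scores for every (donor, receiver, metabolite).

    ``medium`` defaults to the community-specific minimal medium (the
    smallest shared-mode medium on which every member grows). For each
    receiver, SCS is the fraction of its inclusion-minimal donor sets
    containing the donor (0 for every donor when the receiver is
    self-sufficient on the medium); MUS is the fraction of the receiver's
    minimal uptake requirements (its minimal media) containing the
    metabolite; MPS is 1 when the donor can secrete the metabolite at
    nonzero flux while growing on the medium. Only records with a
    positive product are returned; inorganic metabolites are excluded.
    """
    if len(models) > max_members:
        raise ValueError(
            f"community of {len(models)} exceeds the exact-enumeration bound "
            f"({max_members}); split or raise max_members consciously"
        )
    if len(models) < 2:
        raise ValueError("need >= 2 community members")
    by_id = {m.model_id: m for m in models}
    if medium is None:
        medium = smallest_community_medium(models, "shared", g_min=g_min)
        if medium is None:
            raise ValueError("no feasible community medium")
    medium = frozenset(medium)

    organics: set[str] = set()
    for m in models:
        organics |= set(m.extracellular(organic_only=exclude_inorganic))
        if not exclude_inorganic:
            organics |= set(m.extracellular())

    scs: dict[tuple[str, str], float] = {}
    mus: dict[tuple[str, str], float] = {}
    for r in sorted(by_id):
        donors = _minimal_donor_sets(by_id, r, medium, g_min)
        others = sorted(set(by_id) - {r})
        if donors is None or not donors:
            for d in others:
                scs[(d, r)] = 0.0
        else:
            for d in others:
                scs[(d, r)] = sum(d in s for s in donors) / len(donors)
        media = minimal_media(by_id[r], g_min=g_min)
        for met in sorted(organics):
            mus[(met, r)] = (
                sum(met in s for s in media) / len(media) if media else 0.0
            )

    mps: dict[tuple[str, str], float] = {}
    for d in sorted(by_id):
        for met in sorted(organics):
            mps[(met, d)] = 1.0 if _can_secrete(by_id[d], met, medium, g_min) else 0.0

    records: list[PairwiseScore] = []
    for d in sorted(by_id):
        for r in sorted(by_id):
            if d == r:
                continue
            for met in sorted(organics):
                score = PairwiseScore(d, r, met, scs[(d, r)], mus[(met, r)], mps[(met, d)])
                if score.smetana > 0:
                    records.append(score)
    return records


def community_scores(records: Iterable[PairwiseScore], n: int) -> tuple[float, float]:
    """Sum of smetana scores and its size-normalized version.

    The normalization divides by the number of potential genome-genome
    interactions, N(N-1)/2.
    """
    if n < 2:
        raise ValueError("community size must be >= 2")
    total = float(sum(r.smetana for r in records))
    return total, total / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# Transporters and metabolite categories
# ---------------------------------------------------------------------------


def _base_compartment(met_id: str) -> tuple[str, str]:
    base, _, comp = met_id.rpartition("_")
    return (base, comp) if base else (met_id, "")


def classify_transporters(
    model: MetabolicModel, mechanism_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Tabulate transport reactions by mechanism and direction.

    A reaction is a transporter when it is annotated as such or when it
    moves a base metabolite between the extracellular and an internal
    compartment. Reversible transporters are duplicated and counted in
    both directions; unclassifiable mechanisms fall back to "other".
    """
    mechanism_map = mechanism_map or {}
    rows = []
    for rid, rxn in sorted(model.reactions.items()):
        if rid.startswith("EX_") or rid == model.biomass_reaction_id:
            continue
        moved_in, moved_out = [], []
        bases: dict[str, dict[str, float]] = {}
        for met, coef in rxn.stoich.items():
            base, comp = _base_compartment(met)
            bases.setdefault(base, {})[comp] = coef
        for base, comps in bases.items():
            if "e" in comps and any(c != "e" for c in comps):
                if comps["e"] < 0:
                    moved_in.append(base)
                else:
                    moved_out.append(base)
        annotated = rxn.transport is not None
        if not annotated and not moved_in and not moved_out:
            continue
        mech = None
        if rxn.transport:
            mech = rxn.transport.get("mechanism")
        mech = mech or mechanism_map.get(rid) or "other"
        if mech not in TRANSPORTER_MECHANISMS:
            mech = "other"
        directions = []
        if rxn.transport and rxn.transport.get("direction") in ("import", "export"):
            directions = [rxn.transport["direction"]]
        else:
            forward = "import" if (moved_in or not moved_out) else "export"
            directions = [forward]
        if rxn.reversible:
            directions = ["import", "export"]
        for direction in directions:
            rows.append(
                {
                    "reaction_id": rid,
                    "mechanism": mech,
                    "direction": direction,
                    "genes": ";".join(rxn.genes),
                }
            )
    return pd.DataFrame(rows, columns=["reaction_id", "mechanism", "direction", "genes"])


def transporter_activity(
    transporters: pd.DataFrame, expressed: Iterable[str]
) -> pd.DataFrame:
    """Flag transporters as active when any of their genes is expressed.

    Meta-omics gene detection is sparse, so a transporter complex counts
    as active as soon as one of its components is transcribed. Reactions
    without genes are inactive and flagged in the ``no_genes`` column.
    """
    expressed = set(expressed)
    out = transporters.copy()
    genes = out["genes"].fillna("").str.split(";")
    out["no_genes"] = genes.apply(lambda g: not any(g))
    out["active"] = genes.apply(lambda g: any(x in expressed for x in g if x))
    return out


def categorize_metabolites(
    metabolite_ids: Iterable[str], category_map: Mapping[str, str]
) -> dict[str, str]:
    """Total lookup of metabolite categories; unmapped ids are 'uncategorized'."""
    return {m: category_map.get(m, "uncategorized") for m in metabolite_ids}
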