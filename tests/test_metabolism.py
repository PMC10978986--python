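"""Growth checks, minimal media, MRO/MIP and pairwise cross-feeding scores."""

from itertools import combinations

import numpy as np
import pytest

from ecometab import metabolism as mb
from ecometab import synthetic
from ecometab.metabolism import MetabolicModel, Metabolite, Reaction


def clone(model: MetabolicModel, new_id: str) -> MetabolicModel:
    c = MetabolicModel.from_json(model.to_json())
    c.model_id = new_id
    return c


class TestGrowth:
    def test_prototroph_grows_on_designed_medium(self, crossfeed_models):
        assert mb.check_growth(crossfeed_models["p1"], {"glc_e"}).grows

    def test_auxotroph_needs_its_metabolite(self, crossfeed_models):
        r1 = crossfeed_models["r1"]
        assert not mb.check_growth(r1, {"glc_e"}).grows
        assert mb.check_growth(r1, {"glc_e", "vitb1_e"}).grows

    def test_empty_medium_blocks_growth(self, crossfeed_models):
        assert not mb.check_growth(crossfeed_models["p1"], set()).grows

    def test_obligate_pair_grows_in_shared_community(self, crossfeed_models):
        com = mb.build_community(
            [crossfeed_models["d1"], crossfeed_models["r1"]], "shared"
        )
        res = mb.check_community_growth(
            com, {"glc_e"}, require=["d1"], maximize="r1"
        )
        assert res.grows

    def test_private_mode_blocks_cross_feeding(self, crossfeed_models):
        com = mb.build_community(
            [crossfeed_models["d1"], crossfeed_models["r1"]], "private"
        )
        res = mb.check_community_growth(
            com, {"glc_e"}, require=["d1"], maximize="r1"
        )
        assert not res.grows


def _chain_model(model_id, requires_all=(), requires_any=()):
    """Tiny hand-built model: biomass from bm_c, importable nutrients.

    ``requires_all``: every metabolite needed (AND); ``requires_any``:
    alternative substrates, any one suffices (OR).
    """
    mets = {"bm_c": Metabolite("bm_c", compartment="c")}
    rxns = {"BIOMASS": Reaction("BIOMASS", {"bm_c": -1.0})}
    stoich_all = {"bm_c": 1.0}
    for m in requires_all:
        mets[f"{m}_e"] = Metabolite(f"{m}_e", compartment="e", mw=100.0)
        mets[f"{m}_c"] = Metabolite(f"{m}_c", compartment="c")
        rxns[f"EX_{m}_e"] = Reaction(f"EX_{m}_e", {f"{m}_e": -1.0})
        rxns[f"T_{m}"] = Reaction(f"T_{m}", {f"{m}_e": -1.0, f"{m}_c": 1.0})
        stoich_all[f"{m}_c"] = -1.0
    if requires_all:
        rxns["MAKE_bm"] = Reaction("MAKE_bm", stoich_all)
    for m in requires_any:
        mets[f"{m}_e"] = Metabolite(f"{m}_e", compartment="e", mw=100.0)
        mets[f"{m}_c"] = Metabolite(f"{m}_c", compartment="c")
        rxns[f"EX_{m}_e"] = Reaction(f"EX_{m}_e", {f"{m}_e": -1.0})
        rxns[f"T_{m}"] = Reaction(f"T_{m}", {f"{m}_e": -1.0, f"{m}_c": 1.0})
        rxns[f"MAKE_bm_{m}"] = Reaction(f"MAKE_bm_{m}", {f"{m}_c": -1.0, "bm_c": 1.0})
    return MetabolicModel(model_id, mets, rxns, "BIOMASS")


class TestMinimalMedia:
    def test_single_requirement(self):
        m = _chain_model("m", requires_all=["a"])
        assert mb.minimal_media(m) == [frozenset({"a_e"})]

    def test_and_requirement(self):
        m = _chain_model("m", requires_all=["a", "b"])
        assert mb.minimal_media(m) == [frozenset({"a_e", "b_e"})]

    def test_or_requirement(self):
        m = _chain_model("m", requires_any=["a", "b"])
        assert set(mb.minimal_media(m)) == {frozenset({"a_e"}), frozenset({"b_e"})}

    def test_matches_all_subsets_oracle(self, crossfeed_models):
        """Brute force: test growth of every candidate subset, keep the
        inclusion-minimal growing ones."""
        for model in crossfeed_models.values():
            cand = [
                m for m in model.extracellular(organic_only=True)
                if f"EX_{m}" in model.reactions
            ]
            growing = [
                frozenset(s)
                for k in range(len(cand) + 1)
                for s in combinations(cand, k)
                if mb.check_growth(model, set(s)).grows
            ]
            oracle = [
                s for s in growing if not any(t < s for t in growing)
            ]
            assert set(mb.minimal_media(model)) == set(oracle)

    def test_molweight_weighting(self):
        m = _chain_model("m", requires_any=["a", "b"])
        m.metabolites["a_e"].mw = 500.0
        m.metabolites["b_e"].mw = 50.0
        assert mb.minimal_medium(m, weighting="molweight") == frozenset({"b_e"})

    def test_infeasible_model_gives_empty_result(self):
        m = _chain_model("m", requires_all=["a"])
        del m.reactions["EX_a_e"]  # nutrient can never enter
        assert mb.minimal_media(m) == []


class TestMRO:
    def test_identical_pair_full_overlap(self, prototroph_pair):
        assert mb.mro(prototroph_pair) == pytest.approx(1.0)

    def test_disjoint_requirements(self):
        a = _chain_model("a", requires_all=["x"])
        b = _chain_model("b", requires_all=["y"])
        assert mb.mro([a, b]) == pytest.approx(0.0)

    def test_partial_overlap_hand_computed(self):
        a = _chain_model("a", requires_all=["x", "y"])
        b = _chain_model("b", requires_all=["y", "z"])
        # M_a = {x,y}, M_b = {y,z}: |intersection| = 1, min size = 2
        assert mb.mro([a, b]) == pytest.approx(0.5)

    def test_needs_two_members_with_requirements(self, prototroph_pair):
        with pytest.raises(ValueError):
            mb.mro([prototroph_pair[0]])


class TestMIP:
    def test_identical_prototrophs_share_nothing(self, prototroph_pair):
        assert mb.mip(prototroph_pair) == 0

    def test_obligate_pair_saves_one_metabolite(self, crossfeed_models):
        assert mb.mip([crossfeed_models["d1"], crossfeed_models["r1"]]) == 1

    def test_non_negative_on_mixed_communities(self, crossfeed_models):
        trio = [crossfeed_models[k] for k in ("d1", "r1", "p1")]
        assert mb.mip(trio) >= 0


def _oracle_detailed(models, medium, g_min=1e-4):
    """Naive all-subsets enumeration of SCS/MUS/MPS (independent coding)."""
    by_id = {m.model_id: m for m in models}
    organics = set()
    for m in models:
        organics |= set(m.extracellular(organic_only=True))
    out = {}
    for r in by_id:
        others = sorted(set(by_id) - {r})
        # donor sets
        if mb.check_growth(by_id[r], medium, g_min).grows:
            minimal_donors = None
        else:
            growing = []
            for k in range(1, len(others) + 1):
                for D in combinations(others, k):
                    com = mb.build_community([by_id[r]] + [by_id[d] for d in D])
                    if mb.check_community_growth(
                        com, medium, require=D, maximize=r, g_min=g_min
                    ).grows:
                        growing.append(frozenset(D))
            minimal_donors = [s for s in growing if not any(t < s for t in growing)]
        # uptake sets: all subsets of importable organics
        cand = [
            m for m in by_id[r].extracellular(organic_only=True)
            if f"EX_{m}" in by_id[r].reactions
        ]
        growing_U = [
            frozenset(s)
            for k in range(len(cand) + 1)
            for s in combinations(cand, k)
            if mb.check_growth(by_id[r], set(s), g_min).grows
        ]
        minimal_U = [s for s in growing_U if not any(t < s for t in growing_U)]
        for d in others:
            for met in sorted(organics):
                if minimal_donors is None or not minimal_donors:
                    scs = 0.0
                else:
                    scs = sum(d in s for s in minimal_donors) / len(minimal_donors)
                mus = (
                    sum(met in s for s in minimal_U) / len(minimal_U)
                    if minimal_U else 0.0
                )
                mps = 1.0 if mb._can_secrete(by_id[d], met, medium, g_min) else 0.0
                out[(d, r, met)] = scs * mus * mps
    return {k: v for k, v in out.items() if v > 0}


class TestDetailedScores:
    def test_planted_obligate_crossfeed_scores_one(self, crossfeed_models):
        records = mb.detailed_scores(
            [crossfeed_models["d1"], crossfeed_models["r1"]]
        )
        planted = [r for r in records if r.metabolite == "vitb1_e"]
        assert len(planted) == 1
        rec = planted[0]
        assert (rec.donor, rec.receiver) == ("d1", "r1")
        assert rec.scs == rec.mus == rec.mps == rec.smetana == 1.0

    def test_prototrophic_receiver_scores_zero(self, crossfeed_models):
        records = mb.detailed_scores(
            [crossfeed_models["d1"], crossfeed_models["p1"]]
        )
        assert all(r.receiver != "p1" or r.smetana == 0 for r in records)
        assert not [r for r in records if r.receiver == "p1"]

    def test_matches_brute_force_oracle(self, crossfeed_models):
        models = [crossfeed_models[k] for k in ("d1", "r1", "p1")]
        medium = mb.smallest_community_medium(models)
        records = mb.detailed_scores(models, medium=medium)
        impl = {(r.donor, r.receiver, r.metabolite): r.smetana for r in records}
        assert impl == pytest.approx(_oracle_detailed(models, medium))

    def test_adding_isolated_prototroph_preserves_existing_records(
        self, crossfeed_models
    ):
        pair = [crossfeed_models["d1"], crossfeed_models["r1"]]
        medium = mb.smallest_community_medium(pair)
        base = {
            (r.donor, r.receiver, r.metabolite): r.smetana
            for r in mb.detailed_scores(pair, medium=medium)
        }
        trio = pair + [crossfeed_models["p1"]]
        extended = {
            (r.donor, r.receiver, r.metabolite): r.smetana
            for r in mb.detailed_scores(trio, medium=medium)
        }
        for key, value in base.items():
            assert extended.get(key) == pytest.approx(value)

    def test_scores_bounded(self, crossfeed_models):
        records = mb.detailed_scores(
            [crossfeed_models["d1"], crossfeed_models["r1"], crossfeed_models["p1"]]
        )
        for r in records:
            assert 0 <= r.scs <= 1 and 0 <= r.mus <= 1 and 0 <= r.mps <= 1
            assert r.smetana <= min(r.scs, r.mus, r.mps) + 1e-12

    def test_enumeration_bound_enforced(self, prototroph_pair):
        many = [clone(prototroph_pair[0], f"m{i}") for i in range(7)]
        with pytest.raises(ValueError, match="bound"):
            mb.detailed_scores(many)


class TestCommunityScores:
    @pytest.mark.parametrize(
        "n,total,expected",
        [(3, 1.5, 0.5), (2, 1.0, 1.0), (5, 2.0, 0.2)],
    )
    def test_normalization(self, n, total, expected):
        records = [
            mb.PairwiseScore("d", "r", "m", total, 1.0, 1.0)
        ]  # smetana = total
        s, norm = mb.community_scores(records, n)
        assert s == pytest.approx(total)
        assert norm == pytest.approx(expected)

    def test_empty_records(self):
        assert mb.community_scores([], 4) == (0.0, 0.0)


class TestTransporters:
    def test_classification_and_reversible_duplication(self, crossfeed_models):
        model = crossfeed_models["d1"]
        table = mb.classify_transporters(model)
        assert set(table["mechanism"]) <= set(mb.TRANSPORTER_MECHANISMS)
        glc = table[table["reaction_id"] == "T_glc"]
        assert list(glc["direction"]) == ["import"]
        assert list(glc["mechanism"]) == ["ABC"]
        # make a transporter reversible: it must appear in both directions
        model2 = clone(model, "d1rev")
        model2.reactions["T_glc"].lb = -1000.0
        t2 = mb.classify_transporters(model2)
        assert sorted(t2[t2["reaction_id"] == "T_glc"]["direction"]) == [
            "export",
            "import",
        ]

    def test_activity_any_component_suffices(self, crossfeed_models):
        table = mb.classify_transporters(crossfeed_models["d1"])
        genes = table.loc[table["reaction_id"] == "T_glc", "genes"].iloc[0]
        out = mb.transporter_activity(table, {genes.split(";")[0]})
        assert bool(out.loc[out["reaction_id"] == "T_glc", "active"].iloc[0])
        none = mb.transporter_activity(table, set())
        assert not none["active"].any()

    def test_and_rule_single_gene_activates(self):
        mets = {
            "x_e": Metabolite("x_e", compartment="e"),
            "x_c": Metabolite("x_c", compartment="c"),
            "bm_c": Metabolite("bm_c", compartment="c"),
        }
        rxns = {
            "T_x": Reaction("T_x", {"x_e": -1.0, "x_c": 1.0}, gene_rule="gA and gB"),
            "BIOMASS": Reaction("BIOMASS", {"bm_c": -1.0}),
            "MAKE": Reaction("MAKE", {"x_c": -1.0, "bm_c": 1.0}),
            "EX_x_e": Reaction("EX_x_e", {"x_e": -1.0}),
        }
        model = MetabolicModel("m", mets, rxns, "BIOMASS")
        table = mb.classify_transporters(model)
        out = mb.transporter_activity(table, {"gA"})
        assert bool(out.loc[out["reaction_id"] == "T_x", "active"].iloc[0])


def test_categorize_metabolites_total_lookup():
    cats = mb.categorize_metabolites(
        ["aa_arg_e", "mystery"], {"aa_arg_e": "amino acids"}
    )
    assert cats == {"aa_arg_e": "amino acids", "mystery": "uncategorized"}


def test_model_json_round_trip(crossfeed_models):
    model = crossfeed_models["r1"]
    again = MetabolicModel.from_json(model.to_json())
    assert again.to_json() == model.to_json()
    assert mb.minimal_media(again) == mb.minimal_media(model)
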