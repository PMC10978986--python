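"""Community typing, Gini/Jaccard statistics, exchange profiles and ordination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecometab import communities as ct
from ecometab.metabolism import PairwiseScore


def _thr(pd_q05=1.0, score_q95=0.5, n=100):
    return ct.NullThresholds(pd_q05, score_q95, n)


class TestSampling:
    def test_contracts(self):
        pool = [f"g{i}" for i in range(30)]
        comms = ct.sample_random_communities(pool, [3, 4, 5], 50, seed=1)
        assert len(comms) == 50
        for c in comms:
            assert len(c) in (3, 4, 5)
            assert c <= set(pool)

    def test_deterministic(self):
        pool = [f"g{i}" for i in range(20)]
        assert ct.sample_random_communities(pool, [3], 10, seed=7) == \
            ct.sample_random_communities(pool, [3], 10, seed=7)

    def test_size_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            ct.sample_random_communities(["a", "b"], [3], 1, seed=0)


class TestClassification:
    @pytest.mark.parametrize(
        "mean_pd,score,expected",
        [
            (0.5, 0.9, "LPD-HCP"),
            (0.5, 0.2, "LPD-LCP"),
            (1.5, 0.9, "HPD-HCP"),
            (1.5, 0.2, "HPD-LCP"),
            (1.0, 0.5, "HPD-LCP"),  # boundaries: pd >= q05 and score <= q95
        ],
    )
    def test_quadrants(self, mean_pd, score, expected):
        assert ct.classify_community(mean_pd, score, _thr()) == expected

    def test_threshold_quantile_method(self):
        pds = list(range(100))
        scores = list(range(100))
        thr = ct.compute_null_thresholds(pds, scores)
        assert thr.pd_q05 == pytest.approx(np.quantile(pds, 0.05))
        assert thr.score_q95 == pytest.approx(np.quantile(scores, 0.95))

    def test_minimum_null_size(self):
        with pytest.raises(ValueError):
            ct.NullThresholds(0.1, 0.2, 10)

    def test_null_calibration(self):
        """Null draws classify HPD-LCP with frequency ~0.95^2."""
        rng = np.random.default_rng(11)
        null_pd = rng.lognormal(0, 0.4, 1000)
        null_score = rng.lognormal(-2, 0.8, 1000)
        thr = ct.compute_null_thresholds(null_pd, null_score)
        fresh_pd = rng.lognormal(0, 0.4, 1000)
        fresh_score = rng.lognormal(-2, 0.8, 1000)
        labels = [
            ct.classify_community(p, s, thr)
            for p, s in zip(fresh_pd, fresh_score)
        ]
        frac = labels.count("HPD-LCP") / len(labels)
        assert frac == pytest.approx(0.9025, abs=0.04)


class TestGini:
    @pytest.mark.parametrize(
        "capitals,expected",
        [((4, 4, 4), 0.0), ((0, 0, 10), 1.0), ((2, 4), 1 / 3)],
    )
    def test_reference_values(self, capitals, expected):
        assert ct.functional_gini(capitals) == pytest.approx(expected)

    @given(
        values=st.lists(st.integers(0, 50), min_size=2, max_size=8).filter(
            lambda v: sum(v) > 0
        ),
        scale=st.integers(1, 5),
    )
    @settings(derandomize=True, max_examples=60)
    def test_bounded_and_scale_invariant(self, values, scale):
        g = ct.functional_gini(values)
        assert 0.0 <= g <= 1.0 + 1e-12
        assert ct.functional_gini([v * scale for v in values]) == pytest.approx(g)

    def test_capitals_from_ko_sets(self):
        ko = {"a": {"k1", "k2"}, "b": {"k2", "k3"}, "c": set()}
        caps = ct.functional_capitals(["a", "b", "c"], ko)
        assert caps.to_dict() == {"a": 2, "b": 2, "c": 0}

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ct.functional_gini([0, 0])


class TestJaccard:
    def test_values(self):
        assert ct.functional_jaccard({"k1"}, {"k1"}) == 0.0
        assert ct.functional_jaccard({"k1"}, {"k2"}) == 1.0
        assert ct.functional_jaccard({"k1", "k2", "k3"}, {"k2", "k3", "k4"}) == 0.5

    def test_expressed_mode_restriction(self):
        detection = pd.DataFrame(
            {
                "genome_id": ["a", "a", "b", "b"],
                "ko_id": ["k1", "k2", "k2", "k3"],
                "n_samples_detected": [12, 3, 15, 11],
            }
        )
        sets = ct.expressed_ko_sets(detection, min_samples=10)
        assert sets == {"a": {"k1"}, "b": {"k2", "k3"}}

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            ct.functional_jaccard(set(), set())


class TestExchangeProfiles:
    def test_single_record_and_partition_identity(self):
        records = {
            "c1": [
                PairwiseScore("d", "r", "aa_arg_e", 1.0, 0.8, 1.0),  # 0.8
                PairwiseScore("d", "r", "weird_e", 1.0, 0.5, 1.0),   # 0.5
            ],
            "c2": [PairwiseScore("d", "r", "vitb1_e", 1.0, 1.0, 1.0)],
        }
        cats = {"aa_arg_e": "amino acids", "vitb1_e": "B vitamins"}
        prof = ct.exchange_category_profile(records, cats)
        assert prof.loc["c1", "amino acids"] == pytest.approx(0.8)
        assert prof.loc["c1", "uncategorized"] == pytest.approx(0.5)
        assert prof.loc["c2", "B vitamins"] == pytest.approx(1.0)
        # row sums equal each community's smetana sum score
        for cid, recs in records.items():
            assert prof.loc[cid].sum() == pytest.approx(
                sum(r.smetana for r in recs)
            )


class TestPerMetaboliteTests:
    def test_identical_distributions_ns(self):
        scores = pd.DataFrame(
            {"m1": [1.0] * 8, "m2": [0.5] * 8},
            index=[f"c{i}" for i in range(8)],
        )
        groups = {f"c{i}": "A" if i < 4 else "B" for i in range(8)}
        out = ct.per_metabolite_tests(scores, groups)
        assert np.allclose(out["p_bh"], 1.0)
        assert (out["stars"] == "ns").all()

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(3)
        n = 12
        scores = pd.DataFrame(
            {
                "shifted": np.r_[rng.normal(5, 0.3, n), rng.normal(1, 0.3, n)],
                "flat": rng.normal(1, 0.3, 2 * n),
            },
            index=[f"c{i}" for i in range(2 * n)],
        )
        groups = {f"c{i}": "A" if i < n else "B" for i in range(2 * n)}
        out = ct.per_metabolite_tests(scores, groups)
        assert out.loc["shifted", "p_bh"] <= 0.05
        assert out.loc["flat", "stars"] == "ns"

    @pytest.mark.parametrize(
        "p,stars",
        [(5e-5, "****"), (5e-4, "***"), (5e-3, "**"), (0.03, "*"), (0.2, "ns")],
    )
    def test_star_convention(self, p, stars):
        assert ct.significance_stars(p) == stars


class TestNMDS:
    def test_duplicated_rows_land_together(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.1, 1, (3, 4))
        mat = pd.DataFrame(
            np.vstack([base, base[0]]), index=["a", "b", "c", "a2"]
        )
        coords, stress = ct.nmds_ordination(mat, seed=5)
        d_dup = np.linalg.norm(coords.loc["a"] - coords.loc["a2"])
        d_other = np.linalg.norm(coords.loc["a"] - coords.loc["b"])
        assert d_dup < d_other
        assert stress >= 0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.uniform(0.1, 1, (6, 5)))
        c1, s1 = ct.nmds_ordination(mat, seed=2)
        c2, s2 = ct.nmds_ordination(mat, seed=2)
        assert np.allclose(c1.values, c2.values)
        assert s1 == s2

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            ct.nmds_ordination(pd.DataFrame(np.ones((3, 3))), seed=0)


class TestDonorSummaries:
    def test_hub_donor_has_higher_centrality(self):
        genomes = [f"g{i}" for i in range(10)]
        centrality = {g: 0.2 for g in genomes}
        centrality["g0"] = 0.9  # the donor hub
        sizes = {g: 2e6 for g in genomes}
        sizes["g0"] = 4e6
        records = [PairwiseScore("g0", "g1", "aa_arg_e", 1.0, 1.0, 1.0)]
        out = ct.donor_summaries(centrality, sizes, records, genomes)
        assert not out["skipped"]
        assert out["donors"] == ["g0"]
        assert out["centrality"]["donor_median"] > out["centrality"]["non_donor_median"]
        assert "p_corrected" in out["centrality"] and "p_value" in out["genome_size"]

    def test_all_donors_skipped(self):
        records = [PairwiseScore("a", "b", "m", 1.0, 1.0, 1.0),
                   PairwiseScore("b", "a", "m", 1.0, 1.0, 1.0)]
        out = ct.donor_summaries({"a": 1, "b": 2}, {"a": 1, "b": 2}, records, ["a", "b"])
        assert out["skipped"]

    def test_category_restriction(self):
        genomes = ["a", "b", "c", "d"]
        records = [
            PairwiseScore("a", "b", "aa_arg_e", 1.0, 1.0, 1.0),
            PairwiseScore("c", "b", "weird_e", 1.0, 1.0, 1.0),
        ]
        cats = {"aa_arg_e": "amino acids"}
        out = ct.donor_summaries(
            {g: 0.5 for g in genomes}, {g: 1e6 for g in genomes}, records,
            genomes, categories=cats, restrict_to=["amino acids"],
        )
        assert out["donors"] == ["a"]
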