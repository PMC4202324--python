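import numpy as np
import pytest
from scipy import stats

from conftest import make_features
from linecns.cns_annotation import (
    classify_location,
    location_summary,
    nearest_gene,
    synteny_check,
    term_enrichment,
    TargetAssignment,
)
from linecns.genome_io import GenomicInterval
from oracles import classify_per_base

RICE_COMPOSITION = {"intergenic": 70.0, "intron": 24.2, "UTR": 5.8,
                    "3'-UTR": 3.4, "5'-UTR": 2.4}


class TestClassifyLocation:
    def test_inside_five_prime_utr(self, simple_annotation):
        assert classify_location(GenomicInterval("chr1", 1010, 1050), simple_annotation) == "5'-UTR"

    def test_intron(self, simple_annotation):
        assert classify_location(GenomicInterval("chr1", 1600, 1900), simple_annotation) == "intron"

    def test_intergenic(self, simple_annotation):
        assert classify_location(GenomicInterval("chr1", 5000, 5100), simple_annotation) == "intergenic"

    def test_utr_tie_broken_by_larger_overlap(self, simple_annotation):
        # overlaps 3'UTR by 60 bases only
        assert classify_location(GenomicInterval("chr1", 2390, 2460), simple_annotation) == "3'-UTR"

    def test_missing_chromosome_errors(self, simple_annotation):
        with pytest.raises(ValueError, match="absent"):
            classify_location(GenomicInterval("chrX", 0, 10), simple_annotation)

    def test_agrees_with_per_base_oracle(self, simple_annotation, rng):
        for _ in range(200):
            start = int(rng.integers(0, 4000))
            end = start + int(rng.integers(5, 400))
            iv = GenomicInterval("chr1", start, end)
            assert classify_location(iv, simple_annotation) == classify_per_base(
                start, end, simple_annotation
            )


class TestLocationSummary:
    def test_eudicot_row(self):
        summ = location_summary(
            {"intergenic": 17, "intron": 2, "5'-UTR": 4, "3'-UTR": 4},
            {"intergenic": 56.8, "intron": 35.0, "UTR": 8.2},
        )
        assert summ.percentages["intergenic"] == 63.0
        assert summ.percentages["intron"] == 7.4
        assert summ.percentages["UTR"] == 29.6

    def test_monocot_row(self):
        summ = location_summary(
            {"intergenic": 112, "intron": 45, "5'-UTR": 24, "3'-UTR": 23},
            RICE_COMPOSITION,
        )
        assert summ.percentages["intergenic"] == 54.9
        assert summ.percentages["intron"] == 22.1
        assert summ.percentages["UTR"] == 23.0

    def test_all_one_category(self):
        summ = location_summary({"intergenic": 10, "intron": 0, "UTR": 0},
                                RICE_COMPOSITION)
        assert summ.percentages["intergenic"] == 100.0
        assert summ.percentages["intron"] == 0.0

    def test_percentages_recompute_and_sum(self):
        summ = location_summary(
            {"intergenic": 7, "intron": 5, "5'-UTR": 3, "3'-UTR": 2},
            RICE_COMPOSITION,
        )
        total = summ.total
        for cat in ("intergenic", "intron", "UTR"):
            assert summ.percentages[cat] == pytest.approx(
                100.0 * summ.counts[cat] / total, abs=0.05
            )
        s = sum(summ.percentages[c] for c in ("intergenic", "intron", "UTR"))
        assert 99.8 <= s <= 100.2

    def test_z_statistic_one_proportion(self):
        summ = location_summary(
            {"intergenic": 112, "intron": 45, "5'-UTR": 24, "3'-UTR": 23},
            RICE_COMPOSITION,
        )
        n = 204
        phat = 112 / n
        p0 = 0.70
        expected = (phat - p0) / np.sqrt(p0 * (1 - p0) / n)
        assert summ.z["intergenic"] == pytest.approx(expected)
        assert summ.p["intergenic"] == pytest.approx(2 * stats.norm.sf(abs(expected)))

    def test_bad_composition_rejected(self):
        with pytest.raises(ValueError, match="composition"):
            location_summary({"intergenic": 1}, {"intergenic": 50.0, "intron": 20.0, "UTR": 5.0})

    def test_round_half_up(self):
        # 8/27 = 29.629... -> 29.6 ; 9/19 = 47.368 -> 47.4 ; 0.25 style ties go up
        summ = location_summary({"intergenic": 1, "intron": 7, "UTR": 0},
                                RICE_COMPOSITION)
        assert summ.percentages["intergenic"] == 12.5  # 1/8


class TestNearestGene:
    def test_inside_intron(self, simple_annotation):
        t = nearest_gene(GenomicInterval("chr1", 1600, 1700), simple_annotation, "c1")
        assert (t.gene_id, t.relation, t.distance) == ("g1", "inside-intron", 0)

    def test_inside_utr(self, simple_annotation):
        t = nearest_gene(GenomicInterval("chr1", 2500, 2600), simple_annotation, "c1")
        assert (t.gene_id, t.relation, t.distance) == ("g1", "inside-UTR", 0)

    def test_nearest_by_distance_and_strand(self):
        feats = make_features(
            "sp",
            [
                ("chr1", 1000, 2000, "+", "gene", "g1"),
                ("chr1", 5000, 6000, "+", "gene", "g2"),
            ],
        )
        t = nearest_gene(GenomicInterval("chr1", 2300, 2400), feats, "c1")
        assert t.gene_id == "g1"
        assert t.distance == 300
        assert t.relation == "nearest-downstream"  # CNS lies 3' of a + strand gene

    def test_exact_tie_reports_both(self):
        feats = make_features(
            "sp",
            [
                ("chr1", 0, 1000, "+", "gene", "gB"),
                ("chr1", 3000, 4000, "+", "gene", "gA"),
            ],
        )
        t = nearest_gene(GenomicInterval("chr1", 1500, 2500), feats, "c1")
        assert t.distance == 500
        assert t.gene_id == "gA"  # lexicographically smaller primary
        assert t.secondary_gene_id == "gB"

    def test_no_genes_flagged(self):
        feats = make_features("sp", [("chr1", 0, 10, "+", "ncRNA", "n1")])
        t = nearest_gene(GenomicInterval("chr1", 100, 200), feats, "c1")
        assert t.relation == "none" and t.gene_id is None


class TestSynteny:
    @pytest.fixture
    def subject(self):
        return make_features(
            "sub",
            [
                ("chr9", 12_000, 13_000, "+", "gene", "og1"),
                ("chr9", 30_000, 31_000, "+", "gene", "og2"),
            ],
        )

    def _assign(self):
        return TargetAssignment("c1", "g1", "nearest-upstream", 300)

    def test_within_range(self, subject):
        ok = synteny_check(self._assign(), {"g1": "og1"},
                           GenomicInterval("chr9", 10_000, 10_100), subject)
        assert ok is True

    def test_beyond_range(self, subject):
        ok = synteny_check(self._assign(), {"g1": "og2"},
                           GenomicInterval("chr9", 10_000, 10_100), subject)
        assert ok is False

    def test_exact_boundary_inclusive(self, subject):
        ok = synteny_check(self._assign(), {"g1": "og1"},
                           GenomicInterval("chr9", 6_900, 7_000), subject)
        # gene starts at 12000; distance = 5000 exactly
        assert ok is True

    def test_unmapped_gene_unknown(self, subject):
        ok = synteny_check(self._assign(), {}, GenomicInterval("chr9", 0, 10), subject)
        assert ok == "unknown"


class TestTermEnrichment:
    def test_exact_tail_probability(self):
        # N=20, K=5, n=5, k=4: p = (C(5,4)C(15,1) + C(5,5)) / C(20,5) = 76/15504
        universe = [f"g{i}" for i in range(20)]
        members = universe[:5]
        targets = universe[:4] + [universe[10]]
        table = {g: ["T"] for g in members}
        df = term_enrichment(targets, table, universe)
        assert df.loc[0, "p"] == pytest.approx(76 / 15504, rel=1e-12)

    def test_k_zero_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        table = {"g9": ["T"]}
        df = term_enrichment(universe[:3], table, universe)
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_bh_adjustment(self):
        universe = [f"g{i}" for i in range(40)]
        # craft two terms with p ~ {0.01-ish, 0.04-ish}; check BH formula directly
        df = term_enrichment(
            universe[:5],
            {"g0": ["A"], "g1": ["A"], "g2": ["A"], "g5": ["B"], "g0b": ["B"]},
            universe,
        )
        ps = df["p"].to_numpy()
        m = len(ps)
        expected_q = np.minimum.accumulate((ps * m / np.arange(1, m + 1))[::-1])[::-1]
        assert np.allclose(df["q"].to_numpy(), expected_q)

    def test_matches_exhaustive_enumeration_small(self, rng):
        from math import comb

        N, K, n = 18, 6, 7
        universe = [f"g{i}" for i in range(N)]
        members = set(universe[:K])
        targets = list(rng.choice(universe, size=n, replace=False))
        k = len(members & set(targets))
        expected = sum(
            comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)
        ) / comb(N, n)
        df = term_enrichment(targets, {g: ["T"] for g in members}, universe)
        assert df.loc[0, "p"] == pytest.approx(expected, rel=1e-12)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            term_enrichment([], {}, [])
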