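import numpy as np
import pandas as pd
import pytest

from conftest import make_features, random_seq
from linecns.genome_io import GenomicInterval, SpeciesGenome
from linecns.sequence_profiles import (
    MethylationResult,
    at_fraction,
    at_profile,
    constant_model,
    gc_logistic_model,
    hotspot_overlap,
    methylation_overlap,
    occupancy_profile,
    two_proportion_z,
    _windowed_at,
)
from linecns.synthetic_data import (
    CnsPlant,
    GeneModel,
    SimulationConfig,
    preset_at_border,
    sample_noncoding_intervals,
    simulate,
)


def _empty_features():
    return make_features("sp", [])


class TestWindowedAt:
    def test_example_window(self):
        assert _windowed_at("ATGCATGCAT", 10, 1)[0] == pytest.approx(0.6)

    def test_all_a_genome(self):
        vals = _windowed_at("A" * 50, 10, 1)
        assert np.allclose(vals, 1.0)
        assert len(vals) == 41  # span - window + 1


class TestAtProfile:
    def test_all_a_genome_flat_one(self):
        genome = SpeciesGenome("sp", {"chr1": "A" * 5000})
        prof = at_profile(
            [GenomicInterval("chr1", 2400, 2500)], genome, _empty_features(),
            flank=1000, center=20,
        )
        assert np.allclose(prof.at, 1.0)
        assert prof.flank_mean == pytest.approx(1.0)
        assert prof.center_mean == pytest.approx(1.0)

    def test_border_drop_detected(self):
        # study conditions: flank A+T 0.56, element A+T 0.54, 200 elements
        res = simulate(preset_at_border(7))
        cns = res.truth.intervals("R")
        prof = at_profile(cns, res.genomes["R"], res.features["R"])
        assert prof.n_cns == 200
        assert prof.center_mean < prof.flank_mean
        assert prof.p < 0.0005

    def test_flanks_into_coding_excluded(self):
        genome = SpeciesGenome("sp", {"chr1": "A" * 10_000})
        feats = make_features(
            "sp",
            [("chr1", 3000, 3100, "+", "gene", "g1"),
             ("chr1", 3000, 3100, "+", "CDS", "g1")],
        )
        # flank [2500-1000, ...] overlaps the CDS -> excluded
        with pytest.raises(ValueError, match="no CNSs left"):
            at_profile([GenomicInterval("chr1", 3400, 3500)], genome, feats)

    def test_uniform_genome_null_not_significant(self, rng):
        # i.i.d. uniform bases: means near 0.5 and a non-significant per-CNS t
        n_flagged = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            genome = SpeciesGenome("sp", {"chr1": random_seq(r, 300_000, at=0.5)})
            cns = [
                GenomicInterval("chr1", int(s), int(s) + 60)
                for s in np.linspace(1500, 295_000, 100)
            ]
            prof = at_profile(cns, genome, _empty_features())
            se3 = 3 * np.sqrt(0.25 / (100 * 2000))
            assert abs(prof.flank_mean - 0.5) < max(se3, 0.01)
            if prof.p_cns < 0.001:
                n_flagged += 1
        assert n_flagged <= 1


class TestOccupancy:
    def _sim(self):
        cfg = SimulationConfig(
            tree_newick="(R:0.0)root;",
            plants=[CnsPlant(count=12, lineage=None, min_length=80, max_length=120)],
            genes=GeneModel(n_genes=12),
            background_at=0.56,
            cns_at=0.48,  # GC-enriched element cores (still matchable from background)
            seed=9,
        )
        return simulate(cfg)

    def test_constant_model_flat(self):
        res = self._sim()
        cns = res.truth.intervals("R")
        prof = occupancy_profile(
            cns, res.genomes["R"], res.features["R"], constant_model(0.5),
            span=500, seed=1,
        )
        assert np.allclose(prof.cns, 0.5)
        assert np.allclose(prof.control_matched, 0.5)
        assert abs(prof.t) < 1e-9

    def test_gc_model_central_peak(self):
        res = self._sim()
        cns = res.truth.intervals("R")
        prof = occupancy_profile(
            cns, res.genomes["R"], res.features["R"], gc_logistic_model(),
            span=500, seed=1,
        )
        mid = len(prof.cns) // 2
        center = prof.cns[mid - 50 : mid + 50].mean()
        assert center > prof.control_unmatched[mid - 50 : mid + 50].mean()
        flank = prof.cns[:200].mean()
        assert center > flank

    def test_matched_control_at_within_tolerance(self):
        res = self._sim()
        cns = res.truth.intervals("R")
        genome = res.genomes["R"]
        matched = sample_noncoding_intervals(
            genome, res.features["R"], [iv.length for iv in cns],
            at_match=[at_fraction(genome.sequence(iv)) for iv in cns],
            at_tolerance=0.01, seed=3, pad=500,
        )
        for iv, ref in zip(matched, cns):
            assert abs(
                at_fraction(genome.sequence(iv)) - at_fraction(genome.sequence(ref))
            ) <= 0.01 + 1e-12

    def test_bad_model_length_rejected(self):
        res = self._sim()
        cns = res.truth.intervals("R")
        with pytest.raises(ValueError, match="length"):
            occupancy_profile(
                cns, res.genomes["R"], res.features["R"],
                lambda s: np.zeros(len(s) - 1), span=500, seed=1,
            )

    def test_empty_cns_set_rejected(self):
        res = self._sim()
        with pytest.raises(ValueError, match="empty"):
            occupancy_profile([], res.genomes["R"], res.features["R"],
                              constant_model(), span=500, seed=1)


class TestMethylation:
    def test_z_formula_example(self):
        # x1=2/27 vs x2=162/729 -> z ~ -1.834 (closed-form evaluation)
        r = two_proportion_z(2, 27, 162, 729)
        assert r.z == pytest.approx(-1.834, abs=0.001)
        assert r.testable

    def test_z_matches_independent_recomputation(self, rng):
        for _ in range(50):
            n1 = int(rng.integers(5, 100))
            n2 = int(rng.integers(5, 1000))
            x1 = int(rng.integers(0, n1 + 1))
            x2 = int(rng.integers(0, n2 + 1))
            r = two_proportion_z(x1, n1, x2, n2)
            if not r.testable:
                assert (x1 + x2) in (0, n1 + n2)
                continue
            pbar = (x1 + x2) / (n1 + n2)
            z = (x1 / n1 - x2 / n2) / np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
            assert r.z == pytest.approx(z, abs=1e-12)

    def test_no_calls_not_testable(self):
        genome = SpeciesGenome("sp", {"chr1": "ACGT" * 5000})
        calls = pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
        r = methylation_overlap(
            [GenomicInterval("chr1", 100, 200)], calls, genome, _empty_features(),
            n_random_sets=3, seed=1,
        )
        assert not r.testable and np.isnan(r.z)

    def test_single_call_counts_methylated(self):
        genome = SpeciesGenome("sp", {"chr1": "ACGT" * 5000})
        calls = pd.DataFrame(
            [{"chrom": "chr1", "pos": 150, "strand": "+", "context": "CG"}]
        )
        r = methylation_overlap(
            [GenomicInterval("chr1", 100, 200)], calls, genome, _empty_features(),
            n_random_sets=2, seed=1,
        )
        assert r.k_cns == 1 and r.n_cns == 1


class TestHotspots:
    def test_disjoint_zero(self):
        n, lst = hotspot_overlap(
            [GenomicInterval("chr1", 0, 100)], [GenomicInterval("chr1", 500, 900)]
        )
        assert n == 0 and lst == []

    def test_containment_counts(self):
        n, lst = hotspot_overlap(
            [GenomicInterval("chr1", 600, 700)], [GenomicInterval("chr1", 500, 900)]
        )
        assert n == 1

    def test_abutting_half_open_zero(self):
        n, _ = hotspot_overlap(
            [GenomicInterval("chr1", 400, 500)], [GenomicInterval("chr1", 500, 900)]
        )
        assert n == 0
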