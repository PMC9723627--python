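"""Window definition, sequence features, PWM scoring, epigenetic overlap."""

import numpy as np
import pandas as pd
import pytest

from ironomics import features
from ironomics.features import (
    PwmScorer,
    acceptor_window,
    branch_point_features,
    cpg_density,
    default_branch_pwm,
    define_regions,
    donor_window,
    feature_registry,
    gc_content,
    hm_overlap_code,
    presence_flags,
    registry_hash,
)
from ironomics.nome import ChromatinRegionCall


class TestRegions:
    def test_plus_strand_window_arithmetic(self, intron_factory):
        r = define_regions(intron_factory(start=1000, end=2000, strand="+"))
        assert r.ss5 == (900, 1100)
        assert r.ss3 == (1900, 2100)
        assert r.mid == (1400, 1600)

    def test_minus_strand_swaps_labels(self, intron_factory):
        r = define_regions(intron_factory(start=1000, end=2000, strand="-"))
        assert r.ss5 == (1900, 2100)
        assert r.ss3 == (900, 1100)

    def test_short_intron_windows_may_overlap(self, intron_factory):
        r = define_regions(intron_factory(start=1000, end=1150))
        assert r.ss5[1] > r.ss3[0]  # overlapping is permitted

    def test_contig_edge_clipping_flagged(self, intron_factory):
        r = define_regions(intron_factory(start=50, end=500), contig_length=520)
        assert r.clipped and r.ss5[0] == 0


class TestSequenceFeatures:
    @pytest.mark.parametrize("seq,expected", [
        ("GCGC", 1.0), ("ATAT", 0.0), ("GCATN", 0.5)])
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_ambiguous_missing(self):
        assert gc_content("NNNN") is None

    @pytest.mark.parametrize("seq,expected", [
        ("CGCG", 50.0), ("ATAT", 0.0), ("ACGT" * 50, 25.0)])
    def test_cpg_density(self, seq, expected):
        assert cpg_density(seq) == pytest.approx(expected)

    def test_cpg_scan_is_overlap_free(self):
        # CGCGCG: greedy non-overlapping scan finds 3, not 5
        assert cpg_density("CGCGCG") == pytest.approx(100 * 3 / 6)


class TestPwmScorer:
    def toy(self):
        # 3-position PWM with consensus ACG
        m = np.log2(np.array([
            [0.7, 0.1, 0.1, 0.1],
            [0.1, 0.7, 0.1, 0.1],
            [0.1, 0.1, 0.7, 0.1],
        ]) / 0.25)
        return PwmScorer(m)

    def test_consensus_maximizes_score(self):
        pwm = self.toy()
        best = pwm.score("ACG")
        for seq in ("TTT", "ACA", "GCG", "AAA"):
            assert pwm.score(seq) < best

    def test_uniform_pwm_scores_zero(self):
        pwm = PwmScorer(np.zeros((4, 4)))
        assert pwm.score("ACGT") == 0.0

    def test_hand_computed_sum(self):
        pwm = self.toy()
        expected = np.log2(0.7 / 0.25) + 2 * np.log2(0.1 / 0.25)
        assert pwm.score("AAA") == pytest.approx(expected)

    def test_ambiguous_base_missing(self):
        assert self.toy().score("ANG") is None

    def test_estimated_from_sites_recovers_consensus(self):
        sites = ["ACG"] * 50 + ["ACA"] * 5
        pwm = PwmScorer.from_sites(sites)
        assert pwm.score("ACG") > pwm.score("ACA") > pwm.score("TTT")


class TestSpliceWindows:
    def test_donor_window_orientation(self, intron_factory):
        #            0123456789...
        seq = {"chr1": "AAACAGGTAAGTCCCCCCCCCCCCTTTTTTTTTTTTCAGGAA"}
        intron = intron_factory(start=6, end=39, gene="G1",
                                exon5_interval=(0, 6), exon3_interval=(39, 42))
        assert donor_window(intron, seq) == "CAGGTAAGT"
        acc = acceptor_window(intron, seq)
        assert len(acc) == 23 and acc.endswith("AGGAA")

    def test_minus_strand_reverse_complements(self, intron_factory):
        plus = {"chr1": "AAACAGGTAAGTCCCCCCCCCCCCTTTTTTTTTTTTCAGGAA"}
        from ironomics.synthetic import revcomp

        minus_seq = {"chr1": revcomp(plus["chr1"])}
        L = len(plus["chr1"])
        intron = intron_factory(start=L - 39, end=L - 6, strand="-")
        assert donor_window(intron, minus_seq) == "CAGGTAAGT"


class TestBranchPoint:
    def build_seq(self, bp_offset=30, length=300):
        rng = np.random.default_rng(0)
        body = list("T" * length)  # A-free background
        hept = "TACTAAC"
        start = length - bp_offset - len(hept)
        body[start:start + len(hept)] = hept
        return "".join(body)

    def test_planted_consensus_found_at_distance(self, intron_factory):
        seq = {"chr1": self.build_seq(bp_offset=30)}
        intron = intron_factory(start=0, end=300)
        score, dist = branch_point_features(intron, seq)
        assert dist == 30
        consensus_score = default_branch_pwm().score("TACTAAC")
        assert score == pytest.approx(consensus_score)

    def test_a_free_region_missing(self, intron_factory):
        seq = {"chr1": "T" * 300}
        intron = intron_factory(start=0, end=300)
        assert branch_point_features(intron, seq) == (None, None)

    def test_tie_broken_toward_splice_site(self, intron_factory):
        length = 300
        body = list("T" * length)
        for off in (60, 25):  # two identical consensus heptamers
            start = length - off - 7
            body[start:start + 7] = "TACTAAC"
        intron = intron_factory(start=0, end=length)
        _, dist = branch_point_features(intron, {"chr1": "".join(body)})
        assert dist == 25

    def test_short_intron_missing(self, intron_factory):
        seq = {"chr1": self.build_seq()}
        intron = intron_factory(start=0, end=80)
        assert branch_point_features(intron, seq) == (None, None)


class TestHistoneCode:
    def peaks(self):
        return pd.DataFrame([
            dict(chrom="chr1", start=100, end=300, name="p1", score=0,
                 strand=".", signal=5.0, pvalue=-1, qvalue=-1, summit=100),
        ])

    def test_no_peak_is_zero(self):
        code = hm_overlap_code((5000, 5200), "chr1", self.peaks(),
                               np.array([5.0]), strong_threshold=10.0)
        assert code == 0

    def test_weak_peak_is_one(self):
        code = hm_overlap_code((150, 350), "chr1", self.peaks(),
                               np.array([5.0]), strong_threshold=10.0)
        assert code == 1

    def test_threshold_boundary_is_strong(self):
        code = hm_overlap_code((150, 350), "chr1", self.peaks(),
                               np.array([10.0]), strong_threshold=10.0)
        assert code == 2

    def test_missing_pileup_downgrades_to_one(self):
        code = hm_overlap_code((150, 350), "chr1", self.peaks(),
                               np.array([np.nan]), strong_threshold=10.0)
        assert code == 1


class TestPresenceFlags:
    def call(self, start, end, kind="NFR"):
        return ChromatinRegionCall("chr1", start, end, kind, 0.01, 0.3, 0.1, 5)

    def test_overlap_sets_flag(self):
        assert presence_flags((100, 300), [self.call(250, 400)]) == (1, 0)

    def test_bookended_interval_does_not_overlap(self):
        assert presence_flags((100, 300), [self.call(300, 400)]) == (0, 0)

    def test_both_kinds(self):
        calls = [self.call(150, 250), self.call(200, 500, "nucleosome")]
        assert presence_flags((100, 300), calls) == (1, 1)


class TestRegistry:
    def test_registry_size_within_budget(self):
        reg = feature_registry()
        assert len(reg) == len(set(reg)) <= 48

    def test_hash_stable_and_order_sensitive(self):
        assert registry_hash() == registry_hash(feature_registry())
        assert registry_hash(feature_registry()[::-1]) != registry_hash()


def test_assembled_vector_complete_and_pure(small_config, small_dataset,
                                            small_ir_table):
    """One assembled row carries the whole registry, and assembling the same
    inputs twice yields identical values (extraction is pure)."""
    from ironomics import io as iio, nome

    table, introns = small_ir_table
    truth = small_dataset.truth
    ct = small_config.cell_types[0]
    gch = iio.read_cytosine_report(small_dataset.gch_reports[ct])
    cpg = nome.filter_cpg_coverage(
        iio.read_cytosine_report(small_dataset.cpg_reports[ct]))
    donor_pwm = features.build_donor_pwm(introns, truth.sequences)
    acceptor_pwm = features.build_acceptor_pwm(introns, truth.sequences)
    sub = table[(table["cell_type"] == ct)
                & (table["retention_call"] != "ambiguous")]
    r = sub.iloc[0]
    intron = next(i for i in introns if i.intron_id == r["intron_id"])

    def assemble():
        return features.assemble_features(
            intron, r["retention_call"], truth.sequences, cpg, gch, [],
            {m: pd.DataFrame() for m in features.HISTONE_MARKS}, {},
            r["psi5"], r["psi3"], donor_pwm, acceptor_pwm)

    row = assemble()
    assert row is not None
    for name in feature_registry():
        assert name in row
    # histone codes default to 0 without peaks
    assert all(row[f"{m}_ss5"] == 0 for m in features.HISTONE_MARKS)
    assert row == assemble()
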