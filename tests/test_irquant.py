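"""IR quantification: trimmed depth, IRratio, retention calls, intron types."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ironomics import irquant
from ironomics.errors import DomainError, EmptyMeasurementError, InputIntegrityError
from ironomics.irquant import (
    PsiValue,
    bin_introns,
    call_retention,
    compute_irratio,
    compute_psi,
    coverage_fraction,
    exonic_abundance,
    trimmed_intronic_abundance,
)


def oracle_trimmed_mean(values, trim=0.3):
    """Independent sort-slice-mean oracle."""
    v = sorted(values)
    k = int(np.floor(trim * len(v)))
    core = v[k: len(v) - k]
    return sum(core) / len(core)


class TestTrimmedAbundance:
    def test_constant_vector_is_identity(self):
        assert trimmed_intronic_abundance([5, 5, 5, 5, 5]) == 5

    def test_drops_three_lowest_and_highest_of_ten(self):
        assert trimmed_intronic_abundance(list(range(10))) == 4.5

    def test_masked_outlier_is_excluded(self):
        assert trimmed_intronic_abundance([100] + [1] * 9, mask={0}) == 1

    def test_all_masked_raises(self):
        with pytest.raises(EmptyMeasurementError):
            trimmed_intronic_abundance([1, 2], mask={0, 1})

    def test_boolean_mask_equivalent_to_index_mask(self):
        d = [7, 1, 2, 3, 4, 5, 6]
        m = np.zeros(7, dtype=bool)
        m[0] = True
        assert trimmed_intronic_abundance(d, m) == \
            trimmed_intronic_abundance(d, {0})

    @given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False),
                    min_size=1, max_size=200))
    @settings(max_examples=200, deadline=None)
    def test_matches_sort_slice_mean_oracle(self, values):
        assert trimmed_intronic_abundance(values) == \
            pytest.approx(oracle_trimmed_mean(values), rel=1e-12)


class TestIrratio:
    @pytest.mark.parametrize("intronic,exonic,expected",
                             [(10, 30, 0.25), (0, 50, 0.0), (7, 7, 0.5),
                              (0, 0, 0.0)])
    def test_printed_examples(self, intronic, exonic, expected):
        assert compute_irratio(intronic, exonic) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            compute_irratio(-1, 5)

    @given(st.floats(0, 1e4), st.floats(0, 1e4), st.floats(0.01, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_intronic_abundance(self, intronic, exonic, delta):
        assert compute_irratio(intronic + delta, exonic) >= \
            compute_irratio(intronic, exonic)


class TestCoverageFraction:
    def test_half_covered(self):
        assert coverage_fraction([1, 1, 0, 0]) == 0.5

    def test_all_zero(self):
        assert coverage_fraction([0, 0, 0]) == 0.0

    def test_mask_excluded_from_denominator(self):
        assert coverage_fraction([3, 2, 0], mask={2}) == 1.0


class TestExonicAbundance:
    def junctions(self):
        return pd.DataFrame(
            {"chrom": ["chr1"], "donor": [1000], "acceptor": [2000],
             "strand": ["+"], "count": [30], "sample": ["s1"]})

    def test_exact_match(self, intron_factory):
        assert exonic_abundance(self.junctions(), intron_factory(), "s1") == 30

    def test_absent_junction_is_zero(self, intron_factory):
        assert exonic_abundance(self.junctions(),
                                intron_factory(start=1500, end=2500), "s1") == 0

    def test_off_by_one_donor_is_zero(self, intron_factory):
        assert exonic_abundance(self.junctions(),
                                intron_factory(start=999), "s1") == 0

    def test_wrong_strand_is_zero(self, intron_factory):
        assert exonic_abundance(self.junctions(),
                                intron_factory(strand="-"), "s1") == 0

    def test_duplicate_records_rejected(self, intron_factory):
        j = pd.concat([self.junctions()] * 2, ignore_index=True)
        with pytest.raises(InputIntegrityError):
            exonic_abundance(j, intron_factory(), "s1")


class TestCallRetention:
    def psis(self, p5=0.95, p3=0.95):
        return PsiValue("e5", "s", p5), PsiValue("e3", "s", p3)

    def test_retained_when_all_filters_pass(self, measurement_factory):
        m = measurement_factory(irratio=0.25, depth=20, cov=0.95)
        assert call_retention(m, *self.psis(), host_fpkm=5,
                              intron_length=500) == "retained"

    def test_non_retained_band(self, measurement_factory):
        m = measurement_factory(irratio=0.005, depth=3, cov=0.5)
        assert call_retention(m, *self.psis(), host_fpkm=5,
                              intron_length=500) == "non_retained"

    def test_gap_between_bands_is_ambiguous(self, measurement_factory):
        m = measurement_factory(irratio=0.05, depth=20, cov=0.95)
        assert call_retention(m, *self.psis(), host_fpkm=5,
                              intron_length=500) == "ambiguous"

    def test_silent_host_or_long_intron_ineligible(self, measurement_factory):
        m = measurement_factory()
        assert call_retention(m, *self.psis(), 0.5, 500) == "ambiguous"
        assert call_retention(m, *self.psis(), 5, 10_000) == "ambiguous"

    def test_low_psi_blocks_retained_call(self, measurement_factory):
        m = measurement_factory()
        assert call_retention(m, *self.psis(p5=0.8), 5, 500) == "ambiguous"


def test_retention_bands_mutually_exclusive():
    rng = np.random.default_rng(0)
    p5 = PsiValue("e5", "s", 0.95)
    p3 = PsiValue("e3", "s", 0.95)
    for _ in range(500):
        m = irquant.IRMeasurement("i", "s", 0.0, 0.0, rng.uniform(0, 1),
                                  rng.uniform(0, 100), rng.uniform(0, 1))
        retained = (m.irratio >= 0.1 and m.intron_depth >= 10
                    and m.coverage_fraction >= 0.9)
        non_ret = m.irratio <= 0.01 and m.intron_depth < 10
        assert not (retained and non_ret)
        call = call_retention(m, p5, p3, 5, 500)
        if call == "retained":
            assert retained
        if call == "non_retained":
            assert non_ret


class TestIntronTypes:
    def test_clean_constitutive_intron_is_type_a(self, intron_factory):
        assert intron_factory().intron_type == "excluded"  # unclassified default
        assert irquant.classify_intron_type(intron_factory()).intron_type == "A"

    def test_overlapping_exon_makes_type_b(self, intron_factory):
        i = intron_factory(overlaps_known_exon=True)
        assert irquant.classify_intron_type(i).intron_type == "B"

    def test_alternative_flank_makes_type_c(self, intron_factory):
        i = intron_factory(exon3_constitutive=False)
        assert irquant.classify_intron_type(i).intron_type == "C"

    def test_long_intron_excluded(self, intron_factory):
        i = intron_factory(start=0, end=20_000)
        assert irquant.classify_intron_type(i).intron_type == "excluded"

    def test_alternative_flank_with_overlap_excluded(self, intron_factory):
        i = intron_factory(exon5_constitutive=False, overlaps_known_exon=True)
        assert irquant.classify_intron_type(i).intron_type == "excluded"


class TestPsi:
    def junctions(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "donor", "acceptor",
                                           "strand", "count", "sample"])

    def test_full_inclusion(self):
        j = self.junctions([("chr1", 800, 1000, "+", 20, "s"),
                            ("chr1", 1200, 1400, "+", 20, "s")])
        assert compute_psi((1000, 1200), "chr1", "+", j, "s") == 1.0

    def test_partial_skipping(self):
        j = self.junctions([("chr1", 800, 1000, "+", 30, "s"),
                            ("chr1", 1200, 1400, "+", 30, "s"),
                            ("chr1", 800, 1400, "+", 10, "s")])
        assert compute_psi((1000, 1200), "chr1", "+", j, "s") == \
            pytest.approx(0.75)

    def test_no_informative_junctions_undefined(self):
        j = self.junctions([("chr1", 5000, 6000, "+", 10, "s")])
        assert compute_psi((1000, 1200), "chr1", "+", j, "s") is None


class TestBinning:
    def test_printed_boundaries(self):
        out = bin_introns([99, 100, 500, 501], [5, 24.9, 75, 0.5])
        assert list(out["length_bin"]) == ["short", "medium", "medium", "long"]
        assert list(out["expression_bin"]) == ["low", "low", "high", "excluded"]

    def test_fpkm_25_is_medium(self):
        assert bin_introns([200], [25.0])["expression_bin"].iloc[0] == "medium"


def test_annotation_roundtrip_recovers_all_planted_introns(small_dataset,
                                                           small_ir_table):
    """GTF write -> read -> intron extraction is lossless for planted introns."""
    _, introns = small_ir_table
    extracted = {i.intron_id for i in introns}
    planted = set(small_dataset.truth.introns["intron_id"])
    assert planted <= extracted


def test_intron_records_reject_degenerate_intervals(intron_factory):
    with pytest.raises(ValueError):
        intron_factory(start=2000, end=2000)
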