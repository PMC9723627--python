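"""GCH profile matrices, clustering, control matching and GLM adjustment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ironomics import profiles, synthetic
from ironomics.errors import DomainError
from ironomics.profiles import (
    ProfileMatrix,
    aggregate_group_profiles,
    build_profile_matrix,
    cluster_profiles,
    first_vs_internal_stratify,
    h3k36me3_glm_adjust,
    match_controls,
)


def gch_track(rng, length, level_fn, depth=25, spacing=4, origin=0):
    pos = np.cumsum(rng.integers(2, 2 * spacing, size=length))
    pos = pos[pos < length] + origin
    levels = level_fn(pos)
    return synthetic.simulate_methylation_calls(pos, levels, depth, rng, "GCH")


class Anchor:
    def __init__(self, iid, start, end, strand="+"):
        self.intron_id, self.start, self.end, self.strand = iid, start, end, strand


class TestProfileMatrix:
    def test_uniform_methylome_flat_profile(self):
        rng = np.random.default_rng(0)
        calls = gch_track(rng, 2000, lambda p: np.full(len(p), 0.30), depth=60)
        m = build_profile_matrix([Anchor("i1", 1000, 1500)], calls)
        row = m.values.iloc[0].dropna()
        assert 25 <= row.mean() <= 35
        assert m.values.shape[1] == 40

    def test_planted_step_recovered(self):
        rng = np.random.default_rng(1)

        def level(p):
            return np.where(p < 1000, 0.10, 0.40)

        calls = gch_track(rng, 2000, level, depth=100)
        m = build_profile_matrix([Anchor("i1", 1000, 1500)], calls)
        up = m.values.iloc[0][[c for c in m.values.columns if c < 0]].dropna()
        down = m.values.iloc[0][[c for c in m.values.columns if c >= 0]].dropna()
        assert abs(up.mean() - 10) < 5 and abs(down.mean() - 40) < 5

    def test_minus_strand_mirrors_layout(self):
        rng = np.random.default_rng(2)

        def level(p):
            return np.where(p < 1000, 0.10, 0.40)

        calls = gch_track(rng, 2000, level, depth=100)
        plus = build_profile_matrix([Anchor("p", 1000, 1500, "+")], calls)
        # minus-strand intron whose donor is also at genomic 1000
        minus = build_profile_matrix([Anchor("m", 500, 1001, "-")], calls)
        up_minus = minus.values.iloc[0][[c for c in minus.values.columns
                                         if c < 0]].dropna()
        # upstream of the minus-strand donor = genomic right = high level
        assert up_minus.mean() > 30

    def test_bin_size_must_divide_window(self):
        with pytest.raises(ValueError):
            build_profile_matrix([], pd.DataFrame(columns=[
                "pos", "count_methylated", "count_unmethylated"]), bin_size=7)


def test_profile_bins_agree_with_region_methylation():
    """Each matrix bin equals pooled region methylation over the same
    genomic interval (cross-module consistency)."""
    from ironomics.nome import region_methylation

    rng = np.random.default_rng(7)
    calls = gch_track(rng, 2000, lambda p: np.where(p < 1000, 0.1, 0.4),
                      depth=30)
    anchor = Anchor("i1", 1000, 1500)
    m = build_profile_matrix([anchor], calls, bin_size=10)
    row = m.values.iloc[0]
    for offset in m.values.columns:
        a = anchor.start + int(offset)
        expected = region_methylation((a, a + 10), calls)
        if expected is None:
            assert np.isnan(row[offset])
        else:
            assert abs(row[offset] - 100 * expected) < 1e-9


class TestClustering:
    def make_matrix(self, n=60, seed=3):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for k in range(n):
            arch = k % 3
            base = np.full(40, 10.0)
            if arch == 1:
                base[:20] = 50.0
            elif arch == 2:
                base[20:] = 50.0
            rows.append(base + rng.normal(0, 2, 40))
            labels.append(arch)
        values = pd.DataFrame(rows, index=[f"i{k}" for k in range(n)],
                              columns=np.arange(-200, 200, 10))
        return ProfileMatrix(values, 10, "5ss"), np.array(labels)

    def test_row_permutation_invariance(self):
        m, labels = self.make_matrix()
        a = cluster_profiles(m, k=3)
        perm = np.random.default_rng(0).permutation(len(m.values))
        m2 = ProfileMatrix(m.values.iloc[perm], 10, "5ss")
        b = cluster_profiles(m2, k=3)
        joined = pd.concat([a.rename("a"), b.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_well_separated_archetypes_recovered(self):
        m, labels = self.make_matrix()
        got = cluster_profiles(m, k=3)
        assert adjusted_rand_score(labels, got.to_numpy()) == 1.0

    def test_duplicated_rows_cluster_together(self):
        m, _ = self.make_matrix(n=30)
        dup = ProfileMatrix(pd.concat([m.values, m.values.iloc[[0]]
                                       .rename(index={"i0": "i0dup"})]),
                            10, "5ss")
        got = cluster_profiles(dup, k=3)
        assert got["i0"] == got["i0dup"]

    def test_k_one_single_cluster(self):
        m, _ = self.make_matrix(n=10)
        assert set(cluster_profiles(m, k=1)) == {1}

    def test_k_larger_than_rows_rejected(self):
        m, _ = self.make_matrix(n=4)
        with pytest.raises(ValueError):
            cluster_profiles(m, k=5)


class TestAggregation:
    def test_identical_groups_identical_curves(self):
        m, _ = TestClustering().make_matrix(n=12)
        curves = aggregate_group_profiles({"a": m, "b": m})
        assert np.allclose(curves.loc["a"], curves.loc["b"])

    def test_empty_group_rejected(self):
        m = ProfileMatrix(pd.DataFrame(columns=np.arange(-200, 200, 10)),
                          10, "5ss")
        with pytest.raises(ValueError):
            aggregate_group_profiles({"empty": m})

    def test_planted_gain_visible_in_curves(self):
        rng = np.random.default_rng(4)
        base = pd.DataFrame(rng.normal(10, 1, (20, 40)),
                            columns=np.arange(-200, 200, 10))
        gain = base + 25.0
        curves = aggregate_group_profiles({
            "non_retained": ProfileMatrix(base, 10, "5ss"),
            "retained": ProfileMatrix(gain, 10, "5ss")})
        assert (curves.loc["retained"] > curves.loc["non_retained"]).all()


class TestMatching:
    def test_controls_within_caliper(self):
        rng = np.random.default_rng(5)
        cases = pd.DataFrame({"intron_id": [f"c{k}" for k in range(20)],
                              "length": rng.integers(100, 1000, 20),
                              "gc_content": rng.uniform(0.4, 0.6, 20)})
        pool = pd.DataFrame({"intron_id": [f"p{k}" for k in range(400)],
                             "length": rng.integers(80, 1200, 400),
                             "gc_content": rng.uniform(0.3, 0.7, 400)})
        matched = match_controls(cases, pool)
        merged = matched.merge(cases, left_on="case_id", right_on="intron_id",
                               suffixes=("_ctrl", "_case"))
        assert len(matched) >= 15
        assert (abs(merged["gc_content_ctrl"]
                    - merged["gc_content_case"]) <= 0.05).all()
        ratio = merged["length_ctrl"] / merged["length_case"]
        assert ((ratio <= 2) & (ratio >= 0.5)).all()

    def test_controls_not_reused(self):
        cases = pd.DataFrame({"intron_id": ["a", "b"], "length": [100, 100],
                              "gc_content": [0.5, 0.5]})
        pool = pd.DataFrame({"intron_id": ["p1"], "length": [100],
                             "gc_content": [0.5]})
        assert len(match_controls(cases, pool)) == 1


class TestGlmAdjust:
    def simulate(self, seed, group_effect=1.0, n=200):
        rng = np.random.default_rng(seed)
        groups = np.array(["retained"] * n + ["non_retained"] * n)
        # accessibility differs by group; counts depend only on accessibility
        gch = np.where(groups == "retained", rng.normal(40, 8, 2 * n),
                       rng.normal(15, 8, 2 * n)).clip(0, 100)
        mu = np.exp(2.0 + 0.02 * gch)
        mu = np.where(groups == "retained", mu * group_effect, mu)
        counts = rng.poisson(mu)
        return counts, gch, groups

    def test_mediated_difference_is_removed(self):
        hits = 0
        for seed in range(20):
            counts, gch, groups = self.simulate(seed)
            out = h3k36me3_glm_adjust(counts, gch, groups)
            if out["p_value"] > 0.05:
                hits += 1
        assert hits >= 16  # mediated-only differences mostly nullified

    def test_direct_group_effect_detected(self):
        hits = 0
        for seed in range(10):
            counts, gch, groups = self.simulate(seed, group_effect=0.5)
            out = h3k36me3_glm_adjust(counts, gch, groups)
            if out["p_value"] < 0.01:
                hits += 1
        assert hits >= 9

    def test_zero_slope_ci_covers_zero(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(10, 300)
        gch = rng.uniform(0, 100, 300)
        groups = np.array(["retained", "non_retained"] * 150)
        out = h3k36me3_glm_adjust(counts, gch, groups)
        lo, hi = out["slope_ci"]
        assert lo <= 0 <= hi

    def test_non_integer_counts_rejected(self):
        with pytest.raises(DomainError):
            h3k36me3_glm_adjust(np.array([1.5, 2.0]), np.array([1.0, 2.0]),
                                np.array(["retained", "non_retained"]))


class TestFirstVsInternal:
    def test_position_map_rules(self):
        a1 = Anchor("i1", 0, 10)
        a2 = Anchor("i2", 20, 30)
        first, internal = first_vs_internal_stratify(
            [a1, a2], tx_position={"i1": 1, "i2": 2})
        assert first == [a1] and internal == [a2]

    def test_first_in_any_transcript_counts_as_first(self):
        a = Anchor("i1", 0, 10)
        # first in transcript A (pos 1), second in transcript B: min rule
        first, internal = first_vs_internal_stratify([a],
                                                     tx_position={"i1": 1})
        assert first == [a]

    def test_annotation_derived_positions(self, small_dataset):
        from ironomics import io as iio, irquant

        annotation = iio.read_gtf(small_dataset.gtf)
        introns = irquant.extract_introns(annotation)
        first, internal = first_vs_internal_stratify(introns, annotation)
        assert len(first) + len(internal) == len(introns)
        assert len(first) > 0 and len(internal) > 0
        # single-transcript genes: exactly one first intron per gene
        t = small_dataset.truth.introns
        planted_first = set(t[t["tx_position"] == 1]["intron_id"])
        got_first = {i.intron_id for i in first}
        assert planted_first <= got_first
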