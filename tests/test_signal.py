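"""Signal matrices, normalization, Wilcoxon signed-rank, percentages."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from escape.intervals import GenomicInterval, ReadTrack, RegionSet
from escape.signal import (
    NormalizationFactors,
    average_profile,
    build_matrix,
    center_intensities,
    center_intensity,
    log2_fold_changes,
    normalization_scale,
    percent_report,
    rank_regions,
    wilcoxon_signed_rank,
)

GENOME = {"chr1": 1_000_000}


def iv(start, end):
    return GenomicInterval("chr1", start, end)


def make_track(positions, strands=None, genome=GENOME):
    pos = np.asarray(positions, dtype=np.int64)
    st = (np.ones(pos.size, np.int8) if strands is None
          else np.asarray(strands, np.int8))
    return ReadTrack({"chr1": pos}, {"chr1": st}, genome=genome)


class TestNormalizationScale:
    def test_rpm(self):
        f = NormalizationFactors(library_reads=2_000_000)
        assert normalization_scale(f) == pytest.approx(0.5)

    def test_spikein_identity_case(self):
        f = NormalizationFactors(1_000_000, spikein_reads=5000, method="spikein")
        assert normalization_scale(f, reference_spikein=5000) == pytest.approx(1.0)

    def test_halving_spikein_doubles_scale(self):
        f1 = NormalizationFactors(10**6, 4000, "spikein")
        f2 = NormalizationFactors(10**6, 2000, "spikein")
        assert normalization_scale(f2, 4000) == pytest.approx(
            2 * normalization_scale(f1, 4000))

    def test_zero_denominators_raise(self):
        with pytest.raises(ValueError):
            normalization_scale(NormalizationFactors(0))
        with pytest.raises(ValueError):
            normalization_scale(NormalizationFactors(10, 0, "spikein"), 100)


class TestBuildMatrix:
    def test_single_read_at_center_one_cell(self):
        track = make_track([10_000])
        m = build_matrix(RegionSet([iv(9_700, 10_300)]), track, scale=1.0,
                         shift=0)
        assert (m.values > 0).sum() == 1
        assert m.values.sum() == 1.0

    def test_empty_track_zero_matrix(self):
        with pytest.warns(UserWarning):
            track = ReadTrack({}, {}, genome=GENOME)
        m = build_matrix(RegionSet([iv(9_700, 10_300)]), track, 1.0)
        assert not m.values.any()

    def test_edge_region_flagged(self):
        track = make_track([500])
        m = build_matrix(RegionSet([iv(200, 800)]), track, 1.0, flank_bp=2000,
                         shift=0)
        assert m.edge_flags[0]

    def test_matches_brute_force(self, rng):
        regions = RegionSet([iv(int(c) - 300, int(c) + 300)
                             for c in rng.integers(5000, 900_000, 10)])
        pos = rng.integers(0, 1_000_000, 5000)
        track = make_track(pos)
        m = build_matrix(regions, track, scale=2.0, bin_bp=50, flank_bp=1000,
                         shift=0)
        for r, region in enumerate(regions):
            lo = region.center - 1000
            for j in range(m.n_bins):
                expected = np.sum((pos >= lo + j * 50) & (pos < lo + (j + 1) * 50))
                assert m.values[r, j] == pytest.approx(2.0 * expected)

    def test_row_sums_conserve_in_window_reads(self, rng):
        regions = RegionSet([iv(50_000, 50_600)])
        pos = rng.integers(40_000, 60_000, 500)
        track = make_track(pos)
        m = build_matrix(regions, track, scale=0.25, flank_bp=2000, shift=0)
        raw = np.sum((pos >= 48_300) & (pos < 52_300))
        assert m.values.sum() / 0.25 == pytest.approx(raw)


class TestCenterRanking:
    def test_reads_outside_window_score_zero(self):
        track = make_track([10_000])
        assert center_intensity(iv(20_000, 20_400), track, 1.0, shift=0) == 0.0

    def test_stable_tie_break(self):
        order = rank_regions(np.array([5.0, 7.0, 5.0, 1.0]))
        assert order.tolist() == [1, 0, 2, 3]

    def test_ranking_matches_brute_force(self, rng):
        centers = rng.choice(np.arange(10_000, 900_000, 1000), 20, replace=False)
        regions = RegionSet([iv(int(c) - 200, int(c) + 200) for c in centers])
        pos = rng.integers(0, 1_000_000, 20_000)
        track = make_track(pos)
        vals = center_intensities(regions, track, 1.0, window=400, shift=0)
        brute = np.array([
            np.sum((pos >= c - 200) & (pos < c + 200)) for c in centers
        ])
        np.testing.assert_allclose(vals, brute)
        np.testing.assert_array_equal(rank_regions(vals),
                                      np.argsort(-brute, kind="stable"))


class TestAverageProfile:
    def test_identical_rows(self):
        track = make_track([10_000, 10_000])
        regions = RegionSet([iv(9_700, 10_300), iv(9_700, 10_300)])
        m = build_matrix(regions, track, 1.0, shift=0)
        np.testing.assert_allclose(average_profile(m), m.values[0])

    def test_empty_matrix_raises(self):
        track = make_track([10])
        m = build_matrix(RegionSet([]), track, 1.0)
        with pytest.raises(ValueError):
            average_profile(m)


class TestLog2FoldChanges:
    def test_identical_tracks_zero(self):
        t = make_track([10_000, 10_050, 10_100])
        regions = RegionSet([iv(9_900, 10_300)])
        lfc = log2_fold_changes(regions, t, t, 1.0, 1.0, shift=0)
        np.testing.assert_allclose(lfc, 0.0)

    def test_known_ratio(self):
        a = make_track([10_000, 10_010, 10_020])
        b = make_track([10_000])
        regions = RegionSet([iv(9_900, 10_300)])
        lfc = log2_fold_changes(regions, a, b, 1.0, 1.0, pseudocount=1, shift=0)
        assert lfc[0] == pytest.approx(1.0)  # log2(4/2)

    def test_antisymmetry(self, rng):
        a = make_track(rng.integers(0, 1_000_000, 2000))
        b = make_track(rng.integers(0, 1_000_000, 2000))
        regions = RegionSet([iv(int(c), int(c) + 500)
                             for c in rng.integers(0, 900_000, 30)])
        fwd = log2_fold_changes(regions, a, b, 0.7, 1.3, shift=0)
        rev = log2_fold_changes(regions, b, a, 1.3, 0.7, shift=0)
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)


def wilcoxon_enumeration(x, alternative):
    """2^n sign-assignment oracle for the exact one-sided p-value."""
    x = np.asarray(x, float)
    x = x[x != 0]
    ranks = sps.rankdata(np.abs(x))
    w_obs = ranks[x > 0].sum()
    hits = total = 0
    for signs in itertools.product([0, 1], repeat=len(x)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if alternative == "greater":
            hits += w >= w_obs
        else:
            hits += w <= w_obs
    return hits / total


class TestWilcoxon:
    def test_all_positive_small(self):
        res = wilcoxon_signed_rank([1, 2, 3], "greater")
        assert res.p_value == pytest.approx(0.125)
        assert res.exact_flag

    def test_all_negative_greater_is_one(self):
        res = wilcoxon_signed_rank([-1, -2, -3], "greater")
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 13))
            x = rng.normal(size=n)
            for alt in ("greater", "less"):
                res = wilcoxon_signed_rank(x, alt)
                assert res.exact_flag
                assert res.p_value == pytest.approx(
                    wilcoxon_enumeration(x, alt), abs=1e-12)

    def test_exact_matches_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(size=15)
            res = wilcoxon_signed_rank(x, "greater")
            sp = sps.wilcoxon(x, alternative="greater", method="exact")
            assert res.p_value == pytest.approx(sp.pvalue, abs=1e-12)

    def test_approximation_close_to_enumeration(self, rng):
        for _ in range(5):
            x = rng.normal(loc=0.3, size=12)
            exact = wilcoxon_enumeration(x, "greater")
            approx = wilcoxon_signed_rank(x, "greater", exact_max_n=0)
            assert not approx.exact_flag
            assert approx.p_value == pytest.approx(exact, abs=0.01)

    def test_ties_force_approximation(self):
        res = wilcoxon_signed_rank([1, 1, 2, 3, -1], "greater")
        assert not res.exact_flag
        assert 0 < res.p_value <= 1

    def test_zeros_dropped_and_all_zero_raises(self):
        res = wilcoxon_signed_rank([0, 1, 2, 3], "greater")
        assert res.n == 3
        with pytest.raises(ValueError, match="no nonzero"):
            wilcoxon_signed_rank([0.0, 0.0])


class TestPercentReport:
    @pytest.mark.parametrize("num,den,dec,expected", [
        (1504, 16003, 1, 9.4),
        (297, 4410, 1, 6.7),
        (4362, 10813, 1, 40.3),
        (1, 2, 0, 50.0),
        (1, 8, 1, 12.5),
        (25, 1000, 0, 3.0),  # 2.5 rounds half-up to 3
    ])
    def test_examples(self, num, den, dec, expected):
        assert percent_report(num, den, dec) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            percent_report(1, 0)
        with pytest.raises(ValueError):
            percent_report(5, 4)
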