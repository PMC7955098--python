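"""Temporal, adipogenic, activation and dependency labelling."""

import numpy as np
import pytest

from escape.dynamics import (
    ActivationParams,
    call_activated_enhancers,
    classify_smarca4_dependency,
    classify_temporal,
    define_adipogenic,
    partition_by_baf_prebinding,
    stratify_mll4,
)
from escape.intervals import (
    GenomicInterval,
    ReadTrack,
    RegionSet,
    overlaps,
    subset_overlapping,
    union,
)

GENOME = {"chr1": 1_000_000}


def iv(start, end):
    return GenomicInterval("chr1", start, end)


def rs(*spans, name=""):
    return RegionSet([iv(s, e) for s, e in spans], name=name)


def track_at(site_counts, genome=GENOME):
    """A track with ``count`` plus-strand reads piled at each site center."""
    pos = []
    for center, count in site_counts:
        pos.extend([center] * count)
    pos = np.asarray(sorted(pos), dtype=np.int64)
    return ReadTrack({"chr1": pos}, {"chr1": np.ones(pos.size, np.int8)},
                     genome=genome)


class TestTemporal:
    def test_identity_all_prebound(self):
        late = rs((0, 100), (500, 600))
        pre, de_novo = classify_temporal(late, late)
        assert len(pre) == 2 and len(de_novo) == 0

    def test_disjoint_all_de_novo(self):
        pre, de_novo = classify_temporal(rs((0, 100)), rs((5000, 5100)))
        assert len(pre) == 0 and len(de_novo) == 1

    def test_fixture_partition(self):
        late = rs(*[(i * 1000, i * 1000 + 100) for i in range(7)])
        early = rs((0, 50), (1000, 1100), (2050, 2200))
        pre, de_novo = classify_temporal(late, early)
        assert len(pre) == 3 and len(de_novo) == 4
        brute = [any(overlaps(x, y) for y in early) for x in late]
        assert sum(brute) == len(pre)


class TestAdipogenic:
    def test_either_factor_includes(self):
        aes = rs((0, 100), (1000, 1100), (2000, 2100))
        out = define_adipogenic(aes, rs(), rs(), rs((1000, 1100)))
        assert [x.start for x in out] == [1000]

    def test_union_equals_three_passes(self, rng):
        def random_set(n):
            starts = rng.integers(0, 500_000, n)
            return RegionSet([iv(int(s), int(s) + 200) for s in starts])

        aes, b, a, p = (random_set(n) for n in (80, 30, 30, 30))
        joint = define_adipogenic(aes, b, a, p)
        merged = union(b, a, p)
        by_union = subset_overlapping(aes, merged)
        assert [(x.start, x.end) for x in joint] == \
               [(x.start, x.end) for x in by_union]


class TestStratifyMll4:
    def test_empty_and_full(self):
        sites = rs((0, 100), (1000, 1100))
        pos, neg = stratify_mll4(sites, rs())
        assert len(pos) == 0 and len(neg) == 2
        pos, neg = stratify_mll4(sites, rs((0, 1_000_000)))
        assert len(pos) == 2 and len(neg) == 0

    def test_partition_sizes(self, rng):
        sites = RegionSet([iv(int(s), int(s) + 100)
                           for s in rng.integers(0, 900_000, 50)])
        pos, neg = stratify_mll4(sites, rs((100_000, 400_000)))
        assert len(pos) + len(neg) == len(sites)


class TestActivation:
    def test_exact_twofold_excluded(self):
        cand = rs((1000, 1400))
        # treated 3 reads, control 1 read, pc=1, equal scale 1 -> ratio exactly 2
        treated = track_at([(1200, 3)])
        control = track_at([(1200, 1)])
        out = call_activated_enhancers(
            cand, treated, control, params=ActivationParams(fragment_shift=0),
            scale_treated=1.0, scale_control=1.0)
        assert len(out) == 0

    def test_pseudocount_with_zero_control(self):
        cand = rs((1000, 1400))
        treated = track_at([(1200, 8)])
        control = track_at([(500_000, 5)])  # no reads at the candidate
        out = call_activated_enhancers(
            cand, treated, control, params=ActivationParams(fragment_shift=0),
            scale_treated=1.0, scale_control=1.0)
        assert len(out) == 1  # ratio (8+1)/(0+1) = 9 > 2

    def test_required_flags_filter(self):
        cand = rs((1000, 1400), (5000, 5400))
        treated = track_at([(1200, 50), (5200, 50)])
        control = track_at([(1200, 2), (5200, 2)])
        out = call_activated_enhancers(
            cand, treated, control,
            required_flags={"SMARCA4": rs((1000, 1400))},
            params=ActivationParams(fragment_shift=0),
            scale_treated=1.0, scale_control=1.0)
        assert [x.start for x in out] == [1000]

    def test_zero_depth_track_raises(self):
        with pytest.warns(UserWarning):
            empty = ReadTrack({}, {}, genome=GENOME)
        with pytest.raises(ValueError, match="zero depth"):
            call_activated_enhancers(rs((0, 100)), empty, track_at([(50, 5)]))

    def test_monotone_in_fold_threshold(self):
        cand = rs(*[(i * 1000, i * 1000 + 400) for i in range(1, 20)])
        treated = track_at([(i * 1000 + 200, 5 * i) for i in range(1, 20)])
        control = track_at([(i * 1000 + 200, 20) for i in range(1, 20)])
        sizes = []
        for fold in (1.5, 2.0, 3.0, 5.0):
            out = call_activated_enhancers(
                cand, treated, control,
                params=ActivationParams(h3k27ac_fold=fold, fragment_shift=0),
                scale_treated=1.0, scale_control=1.0)
            sizes.append(len(out))
        assert sizes == sorted(sizes, reverse=True)

    def test_simulated_recovery(self):
        """40 programmed activated + 60 static enhancers at 4x H3K27ac gain."""
        recovered, false_calls = [], []
        for seed in (11, 22, 33):
            r = np.random.default_rng(seed)
            sites = [(i * 2000 + 1000, i < 40) for i in range(100)]
            cand = rs(*[(c - 300, c + 300) for c, _ in sites])
            base = 30
            treated = track_at(
                [(c, int(r.poisson(base * (4 if act else 1))))
                 for c, act in sites])
            control = track_at([(c, int(r.poisson(base))) for c, _ in sites])
            out = call_activated_enhancers(
                cand, treated, control,
                params=ActivationParams(fragment_shift=0),
                scale_treated=1.0, scale_control=1.0)
            starts = {x.start for x in out}
            recovered.append(sum((c - 300) in starts for c, act in sites if act))
            false_calls.append(sum((c - 300) in starts
                                   for c, act in sites if not act))
        assert all(rec >= 38 for rec in recovered)
        assert all(fc <= 2 for fc in false_calls)


class TestDependency:
    def test_identical_tracks_all_independent(self):
        sites = rs((1000, 1400), (5000, 5400))
        t = track_at([(1200, 20), (5200, 20)])
        indep, dep = classify_smarca4_dependency(
            sites, t, t, params=ActivationParams(fragment_shift=0),
            scale_control=1.0, scale_depleted=1.0)
        assert len(indep) == 2 and len(dep) == 0

    def test_empty_depleted_all_dependent(self):
        sites = rs((1000, 1400))
        ctrl = track_at([(1200, 20)])
        with pytest.warns(UserWarning):
            empty = ReadTrack({}, {}, genome=GENOME)
        indep, dep = classify_smarca4_dependency(
            sites, ctrl, empty, params=ActivationParams(fragment_shift=0),
            scale_control=1.0, scale_depleted=1.0)
        assert len(dep) == 1 and len(indep) == 0

    def test_programmed_split_recovery(self):
        """50/50 split at 4x reduction recovers >= 95% of labels."""
        correct = total = 0
        for seed in (5, 6, 7):
            r = np.random.default_rng(seed)
            sites = [(i * 2000 + 1000, i % 2 == 0) for i in range(100)]
            regions = rs(*[(c - 300, c + 300) for c, _ in sites])
            ctrl = track_at([(c, int(r.poisson(80))) for c, _ in sites])
            depl = track_at(
                [(c, int(r.poisson(80 / 4 if dep else 80)))
                 for c, dep in sites])
            indep, dep_set = classify_smarca4_dependency(
                regions, ctrl, depl, params=ActivationParams(fragment_shift=0),
                scale_control=1.0, scale_depleted=1.0)
            dep_starts = {x.start for x in dep_set}
            for c, is_dep in sites:
                predicted_dep = (c - 300) in dep_starts
                correct += predicted_dep == is_dep
                total += 1
        assert correct / total >= 0.95


class TestBafPrebinding:
    def test_empty_prebinding_all_de_novo(self):
        de_novo, pre = partition_by_baf_prebinding(rs((0, 100)), rs())
        assert len(de_novo) == 1 and len(pre) == 0

    def test_partition_and_consistency_with_temporal(self, rng):
        activated = RegionSet([iv(int(s), int(s) + 100)
                               for s in rng.integers(0, 900_000, 40)])
        baf = rs((0, 300_000))
        de_novo, pre = partition_by_baf_prebinding(activated, baf)
        assert len(de_novo) + len(pre) == len(activated)
        pre2, de2 = classify_temporal(activated, baf)
        assert [(x.start, x.end) for x in pre] == [(x.start, x.end) for x in pre2]
        assert [(x.start, x.end) for x in de_novo] == \
               [(x.start, x.end) for x in de2]
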