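"""Stitching, ranking, the tangent cutoff, and cross-tissue SE comparison."""

import numpy as np
import pytest

from regland.intervals import GeneModel, GenomicInterval, Peak, SignalTrack
from regland.superenhancer import (
    call_super_enhancers,
    cross_tissue_se_specificity,
    find_inflection,
    rank_by_signal,
    stitch_enhancers,
)


def _peaks(spans, chrom="chr1"):
    return [Peak(GenomicInterval(chrom, s, e), name=f"p{i}") for i, (s, e) in enumerate(spans)]


class TestStitching:
    def test_gap_arithmetic(self):
        stitched = stitch_enhancers(_peaks([(100, 200), (5000, 5100), (20000, 20100)]))
        spans = [(r.interval.start, r.interval.end) for r in stitched]
        assert spans == [(100, 5100), (20000, 20100)]  # gap 14,900 > 12,500

    def test_single_peak(self):
        stitched = stitch_enhancers(_peaks([(100, 200)]))
        assert len(stitched) == 1
        assert (stitched[0].interval.start, stitched[0].interval.end) == (100, 200)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            stitch_enhancers(_peaks([(0, 10)]), stitch_distance=-1)

    def test_tss_exclusion_removes_fully_contained_peaks(self):
        genes = [GeneModel("g", GenomicInterval("chr1", 10_000, 12_000), "+")]
        peaks = _peaks([(9_000, 9_500), (40_000, 40_500)])  # first inside TSS +/- 2.5 kb
        stitched = stitch_enhancers(peaks, tss_exclusion=genes)
        assert [(r.interval.start, r.interval.end) for r in stitched] == [(40_000, 40_500)]

    def test_matches_union_find_oracle(self, rng):
        spans = []
        for _ in range(200):
            s = int(rng.integers(0, 2_000_000))
            spans.append((s, s + int(rng.integers(100, 2000))))
        peaks = _peaks(spans)
        stitched = stitch_enhancers(peaks, stitch_distance=12_500)

        # union-find oracle on the gap graph
        parent = list(range(len(peaks)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, a in enumerate(peaks):
            for j, b in enumerate(peaks):
                if i < j and a.interval.chrom == b.interval.chrom:
                    gap = max(
                        a.interval.start - b.interval.end, b.interval.start - a.interval.end
                    )
                    if gap < 12_500:
                        parent[find(i)] = find(j)
        groups = {}
        for i in range(len(peaks)):
            groups.setdefault(find(i), []).append(i)
        oracle = sorted(
            (
                min(peaks[i].interval.start for i in g),
                max(peaks[i].interval.end for i in g),
            )
            for g in groups.values()
        )
        got = sorted((r.interval.start, r.interval.end) for r in stitched)
        assert got == oracle


class TestRanking:
    def test_input_subtraction_and_floor(self):
        regions = stitch_enhancers(_peaks([(0, 100), (1000000, 1000100)]))
        chip = SignalTrack.from_runs([("chr1", 0, 100, 10.0), ("chr1", 1000000, 1000100, 1.0)])
        inp = SignalTrack.from_runs([("chr1", 0, 100, 2.0), ("chr1", 1000000, 1000100, 5.0)])
        ranked = rank_by_signal(regions, chip, inp)
        assert ranked[0].signal == pytest.approx(800.0)  # 1000 - 200
        assert ranked[1].signal == 0.0  # input exceeds ChIP -> floored

    def test_order_invariance(self, rng):
        spans = [(int(s), int(s) + 500) for s in rng.integers(0, 10**6, size=30) * 50]
        spans = sorted(set(spans))
        peaks = _peaks(spans)
        track = SignalTrack.from_runs(
            [("chr1", s, e, float(rng.random() * 5)) for s, e in spans]
        )
        regions = stitch_enhancers(peaks)
        a = rank_by_signal(regions, track)
        b = rank_by_signal(list(reversed(regions)), track)
        assert [(r.interval.start, r.rank) for r in a] == [
            (r.interval.start, r.rank) for r in b
        ]


class TestInflection:
    def test_flat_curve_yields_empty_set(self):
        assert find_inflection([5.0] * 10) == 0

    def test_requires_two_regions(self):
        with pytest.raises(ValueError):
            find_inflection([1.0])

    def test_separates_planted_top_five(self, rng):
        signals = sorted(
            list(rng.normal(1.0, 0.05, size=95).clip(0)) + [1000.0] * 5, reverse=True
        )
        assert find_inflection(signals) == 5

    def test_threshold_property(self, rng):
        for _ in range(100):
            sig = sorted(rng.gamma(1.0, 10.0, size=int(rng.integers(2, 50))), reverse=True)
            n_se = find_inflection(sig)
            if 0 < n_se < len(sig):
                assert min(sig[:n_se]) >= max(sig[n_se:])

    def test_matches_brute_force_tangent_oracle(self, rng):
        def oracle(sig):
            asc = sorted(sig)
            lo, hi = asc[0], asc[-1]
            if hi == lo:
                return 0
            n = len(asc)
            best_i, best_d = 0, None
            for i, s in enumerate(asc):
                d = (s - lo) / (hi - lo) - i / (n - 1)
                if best_d is None or d < best_d:
                    best_d, best_i = d, i
            cut = asc[best_i]
            return sum(1 for s in sig if s > cut)

        for _ in range(1000):
            sig = sorted(
                rng.gamma(rng.uniform(0.5, 3), 10.0, size=int(rng.integers(2, 60))),
                reverse=True,
            )
            assert find_inflection(sig) == oracle(sig)

    def test_call_flags_consistent(self, rng):
        peaks = _peaks([(i * 50_000, i * 50_000 + 1000) for i in range(20)])
        runs = [("chr1", p.interval.start, p.interval.end, 100.0 if i < 3 else 1.0)
                for i, p in enumerate(peaks)]
        call = call_super_enhancers(
            rank_by_signal(stitch_enhancers(peaks), SignalTrack.from_runs(runs))
        )
        assert call.cutoff_index == 3
        assert sum(call.is_super) == 3
        assert all(e.signal >= 99_000 for e in call.super_enhancers)


class TestCrossTissueSpecificity:
    def _sets(self):
        focal = [GenomicInterval("chr1", 0, 1000)]
        return focal

    def test_sharing_rule(self):
        focal = GenomicInterval("chr1", 0, 1000)
        overlapping = GenomicInterval("chr1", 0, 900)
        empty_far = GenomicInterval("chr1", 50_000, 51_000)
        # shared with exactly 1 other tissue -> still specific
        flags = cross_tissue_se_specificity(
            {"f": [focal], "t1": [overlapping], "t2": [empty_far], "t3": [empty_far]},
            focal="f",
        )
        assert flags[focal] is True
        # shared with 2 other tissues -> not specific
        flags = cross_tissue_se_specificity(
            {"f": [focal], "t1": [overlapping], "t2": [overlapping], "t3": [empty_far]},
            focal="f",
        )
        assert flags[focal] is False

    def test_overlap_fraction_rule(self):
        focal = GenomicInterval("chr1", 0, 1000)
        ten_percent = GenomicInterval("chr1", 900, 2000)  # 100 bp of 1000
        flags = cross_tissue_se_specificity(
            {"f": [focal], "t1": [ten_percent], "t2": [ten_percent]},
            focal="f",
            min_overlap_fraction=0.25,
        )
        assert flags[focal] is True  # 10% < 25%, not counted as shared

    def test_focal_absent(self):
        with pytest.raises(KeyError):
            cross_tissue_se_specificity({"a": [], "b": []}, focal="zzz")
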