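"""PWM scoring, exact p-value thresholds, scanning, and enrichment."""

import itertools

import numpy as np
import pytest

from regland.motif import (
    PWM,
    colocalization_by_position,
    dinucleotide_shuffle,
    motif_enrichment_in_regions,
    pwm_logodds_score,
    pwm_pvalue_threshold,
    scan_sequence,
    score_distribution,
    score_tail_probability,
)
from regland.intervals import GenomicInterval, Peak

GRAN = 1e-3


def _sharp_pwm(consensus: str, p: float = 0.97, pseudocount: float = 0.0) -> PWM:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, idx[b]] = p
    return PWM(consensus, mat, pseudocount=pseudocount)


class TestScoring:
    def test_consensus_closed_form(self):
        pwm = _sharp_pwm("ACGT")
        expected = 4 * np.log2(0.97 / 0.25)
        assert pwm_logodds_score("ACGT", pwm) == pytest.approx(expected, abs=1e-9)

    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("U", np.full((6, 4), 0.25), pseudocount=0.0)
        assert pwm_logodds_score("ACGTAC", pwm) == pytest.approx(0.0)

    def test_reverse_complement_symmetry(self):
        pwm = _sharp_pwm("ACGGTA")
        window = "ACGGTA"
        rc_window = "TACCGT"
        assert pwm_logodds_score(rc_window, pwm.reverse_complement()) == pytest.approx(
            pwm_logodds_score(window, pwm)
        )

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            pwm_logodds_score("ACGN", _sharp_pwm("ACGT"))


class TestPvalueThreshold:
    def test_p_one_gives_minimal_score(self):
        pwm = _sharp_pwm("ACGTACGT")
        thr = pwm_pvalue_threshold(pwm, 1.0)
        # quantization rounds each position to the 1e-3-bit grid
        assert thr == pytest.approx(pwm.min_score(), abs=pwm.width * GRAN)

    def test_length_two_full_enumeration(self):
        pwm = _sharp_pwm("AC", p=0.7)
        thr = pwm_pvalue_threshold(pwm, 0.25)
        scores = sorted(
            pwm_logodds_score(a + b, pwm) for a in "ACGT" for b in "ACGT"
        )
        # exactly the 16 dinucleotides; tail mass at thr must be <= 0.25 and
        # extending the tail to the next attainable score level must exceed it
        t_int = round(thr / GRAN)
        q = [round(s / GRAN) for s in scores]
        assert sum(1 for s in q if s >= t_int) / 16 <= 0.25
        lower = sorted({s for s in q if s < t_int})
        if lower:
            assert sum(1 for s in q if s >= lower[-1]) / 16 > 0.25

    def test_length_eight_matches_enumeration(self, rng):
        mat = rng.dirichlet([1.5] * 4, size=8)
        pwm = PWM("m8", mat)
        thr = pwm_pvalue_threshold(pwm, 1e-4)
        # enumerate all 65,536 8-mers on the same quantized grid
        qlod = np.rint(pwm.log_odds() / GRAN).astype(np.int64)
        words = np.array(np.meshgrid(*[range(4)] * 8, indexing="ij")).reshape(8, -1)
        scores = qlod[np.arange(8)[:, None], words].sum(axis=0)
        t_int = int(np.rint(thr / GRAN))
        enum_tail = float(np.mean(scores >= t_int))
        dp_tail = score_tail_probability(pwm, thr)
        assert enum_tail <= 1e-4
        assert dp_tail == pytest.approx(enum_tail, abs=1e-6)
        # the admitted word set is identical to the enumeration-derived one:
        # no attainable score sits between thr and the enumeration threshold
        attainable = np.unique(scores)
        enum_thr = attainable[np.searchsorted(attainable, t_int)]
        assert float(np.mean(scores >= enum_thr)) == pytest.approx(enum_tail, abs=1e-12)

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            pwm_pvalue_threshold(_sharp_pwm("ACGT"), 0.0)


class TestScanning:
    def test_planted_consensus_recovered(self, rng):
        pwm = _sharp_pwm("ACGTTGCA")
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        seq = seq[:500] + "ACGTTGCA" + seq[508:]
        thr = pwm_pvalue_threshold(pwm, 1e-4)
        hits = scan_sequence(seq, pwm, thr)
        plus = [h for h in hits if h.strand == "+" and h.interval.start == 500]
        assert plus and plus[0].interval.end == 508

    def test_reverse_complement_planted_on_minus(self, rng):
        pwm = _sharp_pwm("AACCGGTA")
        rc = "TACCGGTT"
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        seq = seq[:200] + rc + seq[208:]
        hits = scan_sequence(seq, pwm, pwm_pvalue_threshold(pwm, 1e-4))
        minus = [h for h in hits if h.strand == "-" and h.interval.start == 200]
        assert minus

    def test_threshold_above_max_yields_no_hits(self):
        pwm = _sharp_pwm("ACGTACGT")
        assert scan_sequence("ACGTACGT" * 10, pwm, pwm.max_score() + 5.0) == []

    def test_strand_symmetry_whole_sequence(self, rng):
        pwm = _sharp_pwm("ACGGAT", p=0.8)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc_seq = "".join(comp[b] for b in reversed(seq))
        thr = pwm_pvalue_threshold(pwm, 1e-3)
        fwd = scan_sequence(seq, pwm, thr)
        rev = scan_sequence(rc_seq, pwm, thr)
        mirrored = sorted(
            (len(seq) - h.interval.end, {"+": "-", "-": "+"}[h.strand]) for h in rev
        )
        assert sorted((h.interval.start, h.strand) for h in fwd) == mirrored

    def test_hit_rate_calibrated_on_background(self, rng):
        """Per-window hit rate at p=1e-4 is within 3 binomial SDs of 2e-4."""
        mat = np.random.default_rng(5).dirichlet([2, 2, 2, 2], size=10)
        pwm = PWM("dense", mat)
        thr = pwm_pvalue_threshold(pwm, 1e-4)
        n = 1_000_000
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        hits = scan_sequence(seq, pwm, thr)
        n_windows = n - pwm.width + 1
        rate = len(hits) / n_windows
        sd = np.sqrt(2 * n_windows * 1e-4) / n_windows
        assert abs(rate - 2e-4) <= 3 * sd


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
            shuf = dinucleotide_shuffle(seq, rng)
            assert len(shuf) == len(seq)
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

            def counts(s):
                c = {}
                for a, b in zip(s, s[1:]):
                    c[a + b] = c.get(a + b, 0) + 1
                return c

            assert counts(shuf) == counts(seq)


class TestEnrichment:
    def test_planted_motif_strongly_enriched(self, rng):
        pwm = _sharp_pwm("ACGTTACG")
        regions = []
        for i in range(100):
            s = "".join("ACGT"[j] for j in rng.integers(0, 4, 150))
            if i < 80:
                s = s[:70] + "ACGTTACG" + s[78:]
            regions.append(s)
        results = motif_enrichment_in_regions(regions, [pwm], seed=3)
        res = results[0]
        assert res.odds_ratio > 1
        assert res.pvalue < 1e-6

    def test_unattainable_threshold_reports_null(self, rng):
        # a second PWM whose max score cannot reach its explicit threshold
        pwm = _sharp_pwm("ACGTACGTACGT")
        regions = ["".join("ACGT"[j] for j in rng.integers(0, 4, 100)) for _ in range(20)]
        results = motif_enrichment_in_regions(regions, [pwm], seed=3, p_target=1e-9)
        # extremely stringent target: expect no hits and p = 1
        if results[0].table[0][0] == 0 and results[0].table[1][0] == 0:
            assert results[0].pvalue == pytest.approx(1.0)

    def test_region_order_invariance(self, rng):
        pwm = _sharp_pwm("AACCGGTT")
        regions = ["".join("ACGT"[j] for j in rng.integers(0, 4, 120)) for _ in range(30)]
        a = motif_enrichment_in_regions(regions, [pwm], seed=9)
        b = motif_enrichment_in_regions(list(regions), [pwm], seed=9)
        assert a[0].table == b[0].table and a[0].pvalue == b[0].pvalue

    def test_null_motifs_not_systematically_significant(self, rng):
        """Unplanted motifs on random regions: p-values behave like a null."""
        pvals = []
        for seed in range(50):
            local = np.random.default_rng(1000 + seed)
            pwm = PWM("null", local.dirichlet([1.2] * 4, size=8))
            regions = [
                "".join("ACGT"[j] for j in local.integers(0, 4, 120)) for _ in range(30)
            ]
            pvals.append(motif_enrichment_in_regions(regions, [pwm], seed=seed)[0].pvalue)
        pvals = np.asarray(pvals)
        assert np.mean(pvals <= 0.05) <= 0.15
        assert np.median(pvals) > 0.2


class TestColocalization:
    def _hit(self, motif, start, chrom="chr1"):
        from regland.motif import MotifHit

        return MotifHit(
            motif_id=motif,
            interval=GenomicInterval(chrom, start, start + 8),
            strand="+",
            score=10.0,
            pvalue=1e-5,
            threshold=8.0,
        )

    def test_fisher_matches_enumeration(self):
        from math import comb

        peaks, hits, classes = [], [], []
        for i in range(200):
            cls = "proximal" if i < 100 else "distal"
            has = (i < 5) if cls == "proximal" else (i < 120)  # 5/100 vs 20/100
            peaks.append(Peak(GenomicInterval("chr1", i * 1000, i * 1000 + 100)))
            hits.append([self._hit("M", i * 1000 + 10)] if has else [])
            classes.append(cls)
        tables, _ = colocalization_by_position(peaks, hits, classes)
        res = tables["M"]
        # one-sided hypergeometric tail for the 2x2 (distal enrichment)
        a, b = res.table[0]
        c, d = res.table[1]
        n, K, nn = a + b + c + d, a + c, a + b
        tail = sum(
            comb(K, k) * comb(n - K, nn - k) for k in range(a, min(K, nn) + 1)
        ) / comb(n, nn)
        assert res.pvalue == pytest.approx(tail, rel=1e-9)

    def test_spacing_forty_bp(self):
        peaks = [Peak(GenomicInterval("chr1", 0, 500))]
        hits = [[self._hit("anchor", 100), self._hit("partner", 140)]]
        _, spacings = colocalization_by_position(
            peaks, hits, ["distal"], anchor_motif="anchor", partner_motif="partner"
        )
        assert spacings == [40]

    def test_saturated_motif_null_result(self):
        peaks = [Peak(GenomicInterval("chr1", i * 1000, i * 1000 + 100)) for i in range(10)]
        hits = [[self._hit("M", i * 1000 + 1)] for i in range(10)]
        classes = ["proximal"] * 5 + ["distal"] * 5
        tables, _ = colocalization_by_position(peaks, hits, classes)
        assert tables["M"].pvalue == pytest.approx(1.0)
        assert tables["M"].haldane  # zero cells handled with the 0.5 correction

    def test_missing_classification_rejected(self):
        peaks = [Peak(GenomicInterval("chr1", 0, 100))]
        with pytest.raises(ValueError):
            colocalization_by_position(peaks, [[]], ["nearby"])
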