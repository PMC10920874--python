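"""Coordinate conventions, the interval engine, and format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regland import io as rio
from regland.intervals import (
    GenomicInterval,
    Peak,
    SignalTrack,
    interval_overlap,
    signal_sum,
)


class TestGenomicInterval:
    def test_half_open_semantics(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert len(iv) == 100
        assert not iv.overlaps(GenomicInterval("chr1", 200, 300))  # adjacency
        assert iv.overlaps(GenomicInterval("chr1", 199, 300))
        assert iv.overlap_length(GenomicInterval("chr1", 9, 101)) == 1

    @pytest.mark.parametrize(
        "chrom,start,end",
        [("chr1", 5, 5), ("chr1", 10, 5), ("chr1", -1, 5), ("", 0, 5)],
    )
    def test_invalid_intervals_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_summit_must_lie_inside(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert Peak(iv, summit=0).summit_position == 100
        assert Peak(iv).summit_position == 150  # midpoint fallback
        with pytest.raises(ValueError):
            Peak(iv, summit=100)


class TestIntervalOverlap:
    def test_trivial_pairs(self):
        a = [GenomicInterval("chr1", 0, 10)]
        assert interval_overlap(a, [GenomicInterval("chr1", 10, 20)]) == []
        assert interval_overlap(a, [GenomicInterval("chr1", 9, 20)]) == [(0, 0)]
        assert interval_overlap(a, [GenomicInterval("chr2", 0, 10)]) == []

    def test_matches_quadratic_oracle(self, rng):
        def random_set(n):
            out = []
            for _ in range(n):
                chrom = f"chr{rng.integers(1, 4)}"
                s = int(rng.integers(0, 5000))
                out.append(GenomicInterval(chrom, s, s + int(rng.integers(1, 300))))
            return out

        q, s = random_set(1000), random_set(1000)
        got = set(interval_overlap(q, s))
        expected = {
            (i, j)
            for i, qi in enumerate(q)
            for j, sj in enumerate(s)
            if qi.chrom == sj.chrom and qi.start < sj.end and sj.start < qi.end
        }
        assert got == expected


class TestSignalTrack:
    def test_constant_track_area(self):
        track = SignalTrack.from_runs([("chr1", 0, 100, 2.0)])
        assert signal_sum(track, GenomicInterval("chr1", 10, 20)) == pytest.approx(20.0)
        assert signal_sum(track, GenomicInterval("chr1", 500, 600)) == 0.0
        assert signal_sum(track, GenomicInterval("chr9", 0, 10)) == 0.0

    def test_overlapping_runs_rejected(self):
        with pytest.raises(ValueError):
            SignalTrack.from_runs([("chr1", 0, 10, 1.0), ("chr1", 5, 15, 2.0)])

    def test_matches_per_bp_oracle(self, rng):
        edges = np.sort(rng.choice(np.arange(1, 2000), size=40, replace=False))
        runs, per_bp = [], np.zeros(2000)
        for s, e in zip(edges[::2], edges[1::2]):
            v = float(rng.random() * 10)
            runs.append(("chr1", int(s), int(e), v))
            per_bp[s:e] = v
        track = SignalTrack.from_runs(runs)
        for _ in range(50):
            a = int(rng.integers(0, 1900))
            b = a + int(rng.integers(1, 100))
            assert track.sum(GenomicInterval("chr1", a, b)) == pytest.approx(
                per_bp[a:b].sum(), abs=1e-9
            )

    @given(split=st.integers(min_value=1, max_value=999))
    @settings(max_examples=30, deadline=None)
    def test_additive_over_partition(self, split):
        track = SignalTrack.from_runs(
            [("chr1", 0, 300, 1.5), ("chr1", 400, 800, 0.25), ("chr1", 900, 1000, 3.0)]
        )
        whole = track.sum(GenomicInterval("chr1", 0, 1000))
        left = track.sum(GenomicInterval("chr1", 0, split))
        right = track.sum(GenomicInterval("chr1", split, 1000))
        assert left + right == pytest.approx(whole, abs=1e-9)


class TestBedIO:
    def test_bed3_coordinates_and_order(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr2\t0\t50\nchr1\t5\t6\n")
        peaks = rio.read_bed(p)
        assert [pk.interval.chrom for pk in peaks] == ["chr1", "chr2", "chr1"]
        assert (peaks[0].interval.start, peaks[0].interval.end) == (100, 200)
        assert peaks[0].interval.strand == "."

    def test_empty_interval_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t20\nchr1\t5\t5\n")
        with pytest.raises(rio.FormatError, match=":2"):
            rio.read_bed(p)

    def test_round_trip_byte_identical(self, tmp_path):
        text = "chr1\t100\t200\tpeak1\t5\t+\nchr2\t0\t50\tpeak2\t0\t-\n"
        src = tmp_path / "in.bed"
        src.write_text(text)
        dst = tmp_path / "out.bed"
        rio.write_bed(rio.read_bed(src), dst)
        assert dst.read_text() == text


class TestBedgraphIO:
    def test_single_run(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t10\t2.5\n")
        track = rio.read_bedgraph(p)
        assert track.sum(GenomicInterval("chr1", 0, 10)) == pytest.approx(25.0)

    def test_overlap_and_bad_value_errors(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr1\t0\t10\t1.0\nchr1\t5\t15\t2.0\n")
        with pytest.raises(rio.FormatError):
            rio.read_bedgraph(p)
        p.write_text("chr1\t0\t10\tNOPE\n")
        with pytest.raises(rio.FormatError):
            rio.read_bedgraph(p)

    def test_empty_file_queries_zero(self, tmp_path):
        p = tmp_path / "empty.bedgraph"
        p.write_text("")
        track = rio.read_bedgraph(p)
        assert track.sum(GenomicInterval("chr1", 0, 100)) == 0.0


class TestOtherFormats:
    def test_bedpe_round_trip_and_anchor_order(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t5000\t10000\tchr1\t1000\t2000\tl\t0.05\n")
        loops = rio.read_bedpe(p)
        assert loops[0].anchor1.start == 1000  # sorted on read
        assert loops[0].score == pytest.approx(0.05)

    def test_meme_round_trip(self, tmp_path, rng):
        from regland.motif import PWM

        mat = rng.dirichlet([1, 1, 1, 1], size=9)
        pwm = PWM("TEST_MOTIF", mat)
        path = tmp_path / "m.meme"
        rio.write_meme_pwm([pwm], path)
        back = rio.read_meme_pwm(path)
        assert back[0].name == "TEST_MOTIF"
        assert np.allclose(back[0].matrix, pwm.matrix, atol=1e-5)
        assert np.allclose(back[0].background, pwm.background, atol=1e-4)

    def test_snp_positions_converted_to_zero_based(self, tmp_path):
        p = tmp_path / "snps.tsv"
        p.write_text("snp_id\tchrom\tpos\tref\talt\ttrait\nrs1\tchr1\t1\tA\tG\tx\n")
        snps = rio.read_snps(p)
        assert snps[0].pos == 0
        out = tmp_path / "out.tsv"
        rio.write_snps(snps, out)
        assert rio.read_snps(out)[0] == snps[0]

    def test_gene_model_tss_derivation(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text(
            "gene_id\tchrom\tstrand\tstart\tend\nGplus\tchr1\t+\t100\t500\nGminus\tchr1\t-\t100\t500\n"
        )
        genes = rio.read_gene_models(p)
        assert genes[0].tss == 100
        assert genes[1].tss == 499

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"chr1": "ACGTACGTAC", "chr2": "TTTTGGGG"}
        path = tmp_path / "g.fa"
        rio.write_fasta(seqs, path)
        assert rio.read_fasta(path) == seqs
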