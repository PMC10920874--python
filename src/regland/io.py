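"""Readers and writers for the text formats the pipeline touches.

BED3/BED6(+summit), bedGraph, BEDPE loops, FASTA (via Biopython), MEME
minimal motif format, gene-model / expression / SNP / allele-count TSVs
and ChromHMM-style dense state BEDs.  All I/O is UTF-8, tab-delimited.
Malformed records raise :class:`FormatError` naming the offending line.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import (
    GeneModel,
    GenomicInterval,
    LoopRecord,
    Peak,
    SignalTrack,
    SnpRecord,
)
from .states import StateSegmentation


class FormatError(ValueError):
    """A malformed record in an input file."""


def _fields(line: str, path, lineno: int, minimum: int) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < minimum:
        raise FormatError(
            f"{path}:{lineno}: expected >= {minimum} tab-separated fields, got {len(parts)}"
        )
    return parts


# ---------------------------------------------------------------------------
# BED / bedGraph / BEDPE


def read_bed(path) -> list[Peak]:
    """Read BED3/BED6 (optional 7th column: summit offset) into Peaks.

    Input order is preserved; strand defaults to "." when absent.
    """
    peaks: list[Peak] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = _fields(line, path, lineno, 3)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            strand = parts[5] if len(parts) > 5 else "."
            summit = None
            if len(parts) > 6 and parts[6] not in (".", ""):
                summit = int(parts[6])
            try:
                interval = GenomicInterval(parts[0], start, end, strand)
                peaks.append(Peak(interval, summit=summit, score=score, name=name))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks: Sequence[Peak], path, n_columns: int = 6) -> None:
    """Write Peaks as BED; round-trips byte-identically for canonical input."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in peaks:
            iv = p.interval
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if n_columns >= 6 or p.summit is not None:
                cols.append(p.name if p.name is not None else ".")
                cols.append(_num(p.score) if p.score is not None else "0")
                cols.append(iv.strand)
            if p.summit is not None:
                cols.append(str(p.summit))
            fh.write("\t".join(cols) + "\n")


def _num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_bedgraph(path) -> SignalTrack:
    """Read a 4-column bedGraph; overlapping runs are an error."""
    runs: list[tuple[str, int, int, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = _fields(line, path, lineno, 4)
            try:
                runs.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    try:
        return SignalTrack.from_runs(runs)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, value in track.iter_runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def read_bedpe(path) -> list[LoopRecord]:
    """Read loops as BEDPE; optional column 7 is a name, 8 a score/FDR."""
    loops: list[LoopRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = _fields(line, path, lineno, 6)
            try:
                a = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                b = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
                score = float(parts[7]) if len(parts) > 7 and parts[7] != "." else None
                if (a.chrom, a.start, a.end) > (b.chrom, b.start, b.end):
                    a, b = b, a
                loops.append(LoopRecord(a, b, score=score))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return loops


def write_bedpe(loops: Sequence[LoopRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, lp in enumerate(loops):
            a, b = lp.anchor1, lp.anchor2
            score = "." if lp.score is None else f"{lp.score:.6g}"
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\tloop_{i}\t{score}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme_pwm(path):
    """Parse MEME minimal motif format into a list of PWMs."""
    from .motif import PWM  # deferred: motif does not import io

    background = np.array([0.25, 0.25, 0.25, 0.25])
    pwms = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freq.get(b, 0.25) for b in "ACGT"])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {name} has no probability matrix")
            header = lines[i]
            w = None
            toks = header.replace("=", " = ").split()
            for j, tok in enumerate(toks):
                if tok == "w" and toks[j + 1] == "=":
                    w = int(toks[j + 2])
            if w is None:
                raise FormatError(f"{path}: motif {name}: missing w= in matrix header")
            rows = []
            for k in range(w):
                i += 1
                vals = [float(x) for x in lines[i].split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}: motif {name}: matrix row {k} not 4 columns")
                rows.append(vals)
            pwms.append(PWM(name=name, matrix=np.array(rows), background=background.copy()))
        i += 1
    return pwms


def write_meme_pwm(pwms, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.array([0.25] * 4)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip("ACGT", bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_tsv_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix with a header row and row-label first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate row labels")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate column labels")
    return df


def write_tsv_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_gene_models(path) -> list[GeneModel]:
    """Gene-model TSV: gene_id, chrom, strand, start, end (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "strand", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                strand=row.strand,
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tchrom\tstrand\tstart\tend\ttss\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.interval.chrom}\t{g.strand}\t{g.interval.start}"
                f"\t{g.interval.end}\t{g.tss}\n"
            )


def read_snps(path) -> list[SnpRecord]:
    """SNP TSV with 1-based ``pos``; positions are converted to 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"snp_id", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    snps = []
    for row in df.itertuples(index=False):
        snps.append(
            SnpRecord(
                snp_id=str(row.snp_id),
                chrom=row.chrom,
                pos=int(row.pos) - 1,
                ref=row.ref,
                alt=row.alt,
                trait=str(getattr(row, "trait", "")),
                pvalue=float(row.pvalue) if hasattr(row, "pvalue") and pd.notna(row.pvalue) else None,
            )
        )
    return snps


def write_snps(snps: Sequence[SnpRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("snp_id\tchrom\tpos\tref\talt\ttrait\n")
        for s in snps:
            fh.write(f"{s.snp_id}\t{s.chrom}\t{s.pos + 1}\t{s.ref}\t{s.alt}\t{s.trait}\n")


def read_allele_counts(path) -> pd.DataFrame:
    """Allele-count TSV: snp_id, chrom, pos (1-based), ref, alt, ref_count, alt_count."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"snp_id", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
        raise FormatError(f"{path}: negative allele counts")
    return df


def write_allele_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Chromatin-state dense BED


def read_state_bed(path, tissue: str, vocabulary=None) -> StateSegmentation:
    """ChromHMM-style dense BED: chrom, start, end, state mnemonic."""
    segs: list[tuple[str, int, int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = _fields(line, path, lineno, 4)
            try:
                segs.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    try:
        return StateSegmentation(tissue, segs, vocabulary=vocabulary)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_state_bed(seg: StateSegmentation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, state in seg.iter_segments():
            fh.write(f"{chrom}\t{start}\t{end}\t{state}\n")


def intervals_from_peaks(peaks: Iterable[Peak]) -> list[GenomicInterval]:
    return [p.interval for p in peaks]


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length."""
    sizes: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = _fields(line, path, lineno, 2)
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")
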