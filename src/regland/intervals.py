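"""Genomic coordinate primitives and the interval-overlap engine.

All coordinates in this package are 0-based, half-open ``[start, end)``
(BED convention).  SNP tables arrive 1-based and are converted on read.
Overlap logic is strand-blind throughout; strand only enters TSS
derivation and motif scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Peak:
    """A called peak: an interval plus optional summit offset, score, name.

    ``summit`` is a bp offset from ``interval.start`` (narrowPeak
    convention) and must lie inside the interval.
    """

    interval: GenomicInterval
    summit: Optional[int] = None
    score: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.summit is not None and not (0 <= self.summit < len(self.interval)):
            raise ValueError(
                f"summit offset {self.summit} outside [0, {len(self.interval)})"
            )

    @property
    def summit_position(self) -> int:
        """Absolute summit coordinate; the interval midpoint when no summit."""
        if self.summit is None:
            return self.interval.midpoint
        return self.interval.start + self.summit


@dataclass(frozen=True)
class GeneModel:
    """A gene body with a strand-derived TSS (start for +, end-1 for -)."""

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass(frozen=True)
class SnpRecord:
    """A single-nucleotide variant; ``pos`` is the internal 0-based position."""

    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    trait: str = ""
    pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("ref/alt must be single nucleotides")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 0:
            raise ValueError("position must be >= 0")


@dataclass(frozen=True)
class LoopRecord:
    """A chromatin loop between two anchors, sorted so anchor1 <= anchor2."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    score: Optional[float] = None

    def __post_init__(self) -> None:
        a, b = self.anchor1, self.anchor2
        if (a.chrom, a.start, a.end) > (b.chrom, b.start, b.end):
            raise ValueError("loop anchors must be in sorted order (anchor1 <= anchor2)")


def interval_overlap(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs sharing >= 1 bp.

    Chromosomes present in only one of the two sets contribute no pairs.
    Pairs are returned sorted by (query index, subject index).
    """
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(subject):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(query):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        pairs.extend((i, hit.data) for hit in tree.overlap(iv.start, iv.end))
    pairs.sort()
    return pairs


class SignalTrack:
    """Sparse per-chromosome step function of normalized read density.

    Runs are non-overlapping, sorted; uncovered positions have value 0.
    """

    def __init__(self) -> None:
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_runs(
        cls, runs: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            if end <= start:
                raise ValueError(f"empty run [{start}, {end}) on {chrom}")
            if not np.isfinite(value):
                raise ValueError(f"non-finite value {value} on {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, float(value)))
        track = cls()
        for chrom, rs in by_chrom.items():
            rs.sort()
            starts = np.array([r[0] for r in rs], dtype=np.int64)
            ends = np.array([r[1] for r in rs], dtype=np.int64)
            values = np.array([r[2] for r in rs], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                k = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping runs on {chrom}: [{starts[k]},{ends[k]}) and "
                    f"[{starts[k + 1]},{ends[k + 1]})"
                )
            track._runs[chrom] = (starts, ends, values)
        return track

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def iter_runs(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._runs[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def sum(self, interval: GenomicInterval) -> float:
        """Area (value x bp) of the track over ``interval``; 0 if uncovered."""
        runs = self._runs.get(interval.chrom)
        if runs is None:
            return 0.0
        starts, ends, values = runs
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        hi = int(np.searchsorted(starts, interval.end, side="left"))
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], interval.start)
        e = np.minimum(ends[lo:hi], interval.end)
        return float(np.sum((e - s) * values[lo:hi]))

    def mean(self, interval: GenomicInterval) -> float:
        return self.sum(interval) / len(interval)


def signal_sum(track: SignalTrack, interval: GenomicInterval) -> float:
    """Exact area of ``track`` over ``interval`` (module-level convenience)."""
    return track.sum(interval)
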