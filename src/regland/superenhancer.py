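"""ROSE-style super-enhancer calling and cross-tissue comparison.

Peaks are stitched when their gaps fall below a distance threshold
(12.5 kb by convention), ranked by input-subtracted H3K27ac area, and
split into super-enhancers vs typical enhancers at the slope-1 tangent
of the rank-vs-signal curve with both axes scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .intervals import GeneModel, GenomicInterval, Peak, SignalTrack


@dataclass
class StitchedEnhancer:
    """A stitched candidate region with its constituent peaks."""

    interval: GenomicInterval
    constituents: list[str]
    signal: float = 0.0
    rank: Optional[int] = None


@dataclass
class SuperEnhancerCall:
    """Ranked stitched enhancers with the inflection cutoff applied.

    ``cutoff_index`` is the number of super-enhancers: regions with
    1-based rank <= cutoff_index are SEs.  ``scaled_rank``/``scaled_signal``
    are the ascending-sorted [0, 1] curve coordinates the cutoff was
    computed on.
    """

    enhancers: list[StitchedEnhancer]  # descending-signal order
    cutoff_index: int
    is_super: list[bool]
    scaled_rank: np.ndarray = field(default_factory=lambda: np.array([]))
    scaled_signal: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def super_enhancers(self) -> list[StitchedEnhancer]:
        return [e for e, s in zip(self.enhancers, self.is_super) if s]


def stitch_enhancers(
    peaks: Sequence[Peak],
    stitch_distance: int = 12500,
    tss_exclusion: Optional[Sequence[GeneModel]] = None,
    tss_exclusion_window: int = 2500,
) -> list[StitchedEnhancer]:
    """Merge peaks chained by gaps < ``stitch_distance`` into regions.

    With ``tss_exclusion`` supplied, peaks falling fully within
    +/- ``tss_exclusion_window`` of any TSS are removed before stitching
    (the promoter-exclusion step of the conventional procedure).
    """
    if stitch_distance < 0:
        raise ValueError("stitch distance must be non-negative")
    kept = list(peaks)
    if tss_exclusion is not None:
        tss_by_chrom: dict[str, list[int]] = {}
        for g in tss_exclusion:
            tss_by_chrom.setdefault(g.interval.chrom, []).append(g.tss)
        for c in tss_by_chrom:
            tss_by_chrom[c].sort()

        def excluded(p: Peak) -> bool:
            arr = np.asarray(tss_by_chrom.get(p.interval.chrom, []))
            if arr.size == 0:
                return False
            # peak fully inside [tss - w, tss + w] for some TSS t, i.e.
            # t in [end - w - 1, start + w]
            lo_t = p.interval.end - tss_exclusion_window - 1
            hi_t = p.interval.start + tss_exclusion_window
            i0 = int(np.searchsorted(arr, lo_t, side="left"))
            i1 = int(np.searchsorted(arr, hi_t, side="right"))
            return i1 > i0

        kept = [p for p in kept if not excluded(p)]
    by_chrom: dict[str, list[Peak]] = {}
    for p in kept:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    stitched: list[StitchedEnhancer] = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom], key=lambda p: (p.interval.start, p.interval.end))
        cur: list[Peak] = []
        cur_end = -1
        for p in ps:
            if cur and p.interval.start - cur_end >= stitch_distance:
                stitched.append(_make_region(chrom, cur))
                cur = []
            cur.append(p)
            cur_end = max(cur_end, p.interval.end)
        if cur:
            stitched.append(_make_region(chrom, cur))
    return stitched


def _make_region(chrom: str, peaks: list[Peak]) -> StitchedEnhancer:
    start = min(p.interval.start for p in peaks)
    end = max(p.interval.end for p in peaks)
    names = [p.name if p.name is not None else f"{chrom}:{p.interval.start}" for p in peaks]
    return StitchedEnhancer(GenomicInterval(chrom, start, end), constituents=names)


def rank_by_signal(
    stitched: Sequence[StitchedEnhancer],
    h3k27ac: SignalTrack,
    input_track: Optional[SignalTrack] = None,
) -> list[StitchedEnhancer]:
    """Rank regions by input-subtracted H3K27ac area, descending.

    signal = max(0, area(ChIP) - area(input)); ties broken by genomic
    order so the ranking is deterministic regardless of input order.
    """
    out = []
    for region in stitched:
        chip = h3k27ac.sum(region.interval)
        inp = input_track.sum(region.interval) if input_track is not None else 0.0
        out.append(
            StitchedEnhancer(
                interval=region.interval,
                constituents=list(region.constituents),
                signal=max(0.0, chip - inp),
            )
        )
    out.sort(key=lambda e: (-e.signal, e.interval.chrom, e.interval.start))
    for i, e in enumerate(out):
        e.rank = i + 1
    return out


def find_inflection(signals_descending: Sequence[float]) -> int:
    """Number of super-enhancers under the slope-1 tangent cutoff.

    The signals are re-sorted ascending and both axes rescaled to [0, 1];
    the cutoff is the tangent point of a slope-1 line on this curve (the
    index minimizing scaled signal minus scaled rank), and regions whose
    signal is strictly above the cutoff signal are super-enhancers.  A
    flat curve (all signals equal) has no tangent point and yields an
    empty SE set.
    """
    sig = np.asarray(signals_descending, dtype=float)
    if sig.size < 2:
        raise ValueError("need at least 2 regions to locate an inflection")
    if np.any(sig < 0):
        raise ValueError("signals must be non-negative")
    asc = np.sort(sig)
    lo, hi = asc[0], asc[-1]
    if hi == lo:
        return 0
    y = (asc - lo) / (hi - lo)
    x = np.arange(asc.size) / (asc.size - 1)
    cutoff_signal = asc[int(np.argmin(y - x))]
    return int(np.sum(sig > cutoff_signal))


def call_super_enhancers(
    ranked: Sequence[StitchedEnhancer],
) -> SuperEnhancerCall:
    """Apply the inflection cutoff to a descending-ranked enhancer list."""
    signals = [e.signal for e in ranked]
    n_se = find_inflection(signals)
    asc = np.sort(np.asarray(signals, dtype=float))
    lo, hi = asc[0], asc[-1]
    scaled_signal = (asc - lo) / (hi - lo) if hi > lo else np.zeros_like(asc)
    scaled_rank = np.arange(asc.size) / max(asc.size - 1, 1)
    return SuperEnhancerCall(
        enhancers=list(ranked),
        cutoff_index=n_se,
        is_super=[i < n_se for i in range(len(ranked))],
        scaled_rank=scaled_rank,
        scaled_signal=scaled_signal,
    )


def cross_tissue_se_specificity(
    se_sets: dict[str, Sequence[GenomicInterval]],
    focal: str,
    min_overlap_fraction: float = 0.25,
) -> dict[GenomicInterval, bool]:
    """Flag focal SEs shared with at most one other tissue as specific.

    A focal SE is "shared with" tissue t when any SE of t covers at least
    ``min_overlap_fraction`` of the focal SE's length.
    """
    if focal not in se_sets:
        raise KeyError(f"focal tissue {focal!r} absent from SE sets")
    if len(se_sets) < 2:
        raise ValueError("need SE sets for at least 2 tissues")
    result: dict[GenomicInterval, bool] = {}
    others = {t: list(ivs) for t, ivs in se_sets.items() if t != focal}
    for se in se_sets[focal]:
        shared = 0
        need = min_overlap_fraction * len(se)
        for t, ivs in others.items():
            if any(se.overlap_length(iv) >= need and se.overlap_length(iv) > 0 for iv in ivs):
                shared += 1
        result[se] = shared <= 1
    return result
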