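"""Mapping TF peaks onto chromatin states and gene models.

Covers DHS filtering of peak calls, majority-overlap state assignment,
observed/expected state enrichment with one-sided Fisher p-values,
TSS-proximal vs distal classification, and the Poisson tail test for
broad binding enrichment over a region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import poisson

from .intervals import GeneModel, GenomicInterval, Peak, interval_overlap
from .states import StateSegmentation
from .stats import EnrichmentResult, fisher_exact


@dataclass
class StateEnrichment:
    """Per-state observed vs expected peak counts with Fisher p-values."""

    observed: dict[str, int]
    expected: dict[str, float]
    ratio: dict[str, float]
    pvalue: dict[str, float]
    total_peaks: int
    genome_bp: int


def filter_peaks_by_dhs(
    peaks: Sequence[Peak], dhs: Sequence[GenomicInterval]
) -> list[Peak]:
    """Retain peaks overlapping at least one DHS by >= 1 bp."""
    pairs = interval_overlap([p.interval for p in peaks], list(dhs))
    keep = {i for i, _ in pairs}
    return [p for i, p in enumerate(peaks) if i in keep]


def assign_peak_to_state(peak: Peak, segmentation: StateSegmentation) -> str:
    """State with maximal bp overlap; vocabulary order breaks ties."""
    iv = peak.interval
    if not segmentation.has_chrom(iv.chrom):
        raise KeyError(f"chromosome {iv.chrom!r} absent from segmentation")
    overlap_bp: dict[str, int] = {}
    for s, e, state in segmentation.overlapping(iv.chrom, iv.start, iv.end):
        overlap_bp[state] = overlap_bp.get(state, 0) + (e - s)
    if not overlap_bp:
        raise ValueError(f"segmentation does not cover peak {iv.chrom}:{iv.start}-{iv.end}")
    order = {st: k for k, st in enumerate(segmentation.vocabulary)}
    return max(overlap_bp, key=lambda st: (overlap_bp[st], -order[st]))


def state_enrichment(
    assignments: Sequence[str], segmentation: StateSegmentation
) -> StateEnrichment:
    """Observed/expected state composition of assigned peaks.

    expected = total peaks x (state bp / genome bp).  The Fisher 2x2
    compares the peak set against a genome-composition background draw of
    equal size: ((obs in state, obs out), (round(expected), rest)).
    """
    if not assignments:
        raise ValueError("no peak assignments supplied")
    state_bp = segmentation.state_bp()
    genome_bp = sum(state_bp.values())
    total = len(assignments)
    observed: dict[str, int] = {}
    for a in assignments:
        observed[a] = observed.get(a, 0) + 1
    for state, n in observed.items():
        if state_bp.get(state, 0) == 0 and n > 0:
            raise ValueError(
                f"state {state!r} has observed peaks but zero genomic bp"
            )
    expected, ratio, pvalue = {}, {}, {}
    for state in segmentation.vocabulary:
        bp = state_bp.get(state, 0)
        if bp == 0 and state not in observed:
            continue
        exp = total * bp / genome_bp
        obs = observed.get(state, 0)
        expected[state] = exp
        ratio[state] = obs / exp if exp > 0 else float("nan")
        bg_in = int(round(exp))
        res = fisher_exact(
            ((obs, total - obs), (bg_in, total - bg_in)), alternative="greater"
        )
        pvalue[state] = res.pvalue
        observed.setdefault(state, 0)
    return StateEnrichment(
        observed=observed,
        expected=expected,
        ratio=ratio,
        pvalue=pvalue,
        total_peaks=total,
        genome_bp=genome_bp,
    )


def classify_peak_position(
    peak: Peak,
    gene_models: Sequence[GeneModel],
    proximal_window: int = 2000,
) -> str:
    """"proximal" iff the summit (or midpoint) is < window bp from any TSS."""
    if not gene_models:
        raise ValueError("gene models must be non-empty")
    pos = peak.summit_position
    best = None
    for g in gene_models:
        if g.interval.chrom != peak.interval.chrom:
            continue
        d = abs(g.tss - pos)
        best = d if best is None else min(best, d)
    if best is None:
        return "distal"
    return "proximal" if best < proximal_window else "distal"


def classify_peaks(
    peaks: Sequence[Peak],
    gene_models: Sequence[GeneModel],
    proximal_window: int = 2000,
) -> list[str]:
    """Vectorized proximal/distal classification for many peaks."""
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in gene_models:
        tss_by_chrom.setdefault(g.interval.chrom, []).append(g.tss)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}
    out = []
    for p in peaks:
        arr = tss_by_chrom.get(p.interval.chrom)
        if arr is None or arr.size == 0:
            out.append("distal")
            continue
        pos = p.summit_position
        k = int(np.searchsorted(arr, pos))
        d = min(
            [abs(int(arr[j]) - pos) for j in (k - 1, k) if 0 <= j < arr.size]
        )
        out.append("proximal" if d < proximal_window else "distal")
    return out


def poisson_broad_enrichment(
    region: GenomicInterval, observed_count: int, background_rate: float
) -> float:
    """Upper-tail Poisson p-value for broad binding over a region.

    p = P(X >= observed) with X ~ Poisson(rate x region length); the
    observed count is included in the tail.
    """
    if background_rate <= 0:
        raise ValueError("background rate must be positive")
    if observed_count < 0 or int(observed_count) != observed_count:
        raise ValueError("observed count must be a non-negative integer")
    lam = background_rate * len(region)
    return float(poisson.sf(int(observed_count) - 1, lam))
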