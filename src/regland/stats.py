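"""Shared enrichment statistics.

Fisher's exact test (one-sided, hypergeometric), permutation enrichment
against random length-matched background regions, and exact binomial
allelic imbalance.  scipy.stats supplies the distributions; this module
fixes the 2x2 conventions and the permutation-null construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binomtest, hypergeom

from .intervals import GenomicInterval, SnpRecord


@dataclass
class EnrichmentResult:
    """A 2x2 observed/expected test result shared by state, motif and SNP enrichment."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    pvalue: float
    test: str = "fisher_exact_one_sided"
    haldane: bool = False
    name: Optional[str] = None


@dataclass
class PermutationResult:
    """Observed count vs counts in random length-matched region draws."""

    observed: int
    replicates: np.ndarray
    n_perm: int
    pvalue: float
    seed: int

    def __post_init__(self) -> None:
        lo = 1.0 / (1 + self.n_perm)
        if not (lo - 1e-12 <= self.pvalue <= 1.0 + 1e-12):
            raise ValueError("empirical p outside attainable range")


@dataclass
class AlleleImbalanceResult:
    """Exact binomial test of ref/alt read support against 0.5."""

    ref_count: int
    alt_count: int
    depth: int
    ref_fraction: float
    pvalue: float


def fisher_exact(
    table: Sequence[Sequence[int]], alternative: str = "greater"
) -> EnrichmentResult:
    """One-sided Fisher's exact test on a 2x2 table.

    The p-value is the hypergeometric tail in the enrichment direction
    (``alternative="greater"`` tests whether cell (0,0) is large).  The
    odds ratio is (a d)/(b c); if any cell is zero, 0.5 is added to all
    cells (Haldane-Anscombe) and the result is flagged.
    """
    (a, b), (c, d) = (int(table[0][0]), int(table[0][1])), (int(table[1][0]), int(table[1][1]))
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("table grand total must be positive")
    # hypergeometric: draw (a+b) items from n with (a+c) marked; count = a
    if alternative == "greater":
        p = float(hypergeom.sf(a - 1, n, a + c, a + b))
    elif alternative == "less":
        p = float(hypergeom.cdf(a, n, a + c, a + b))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    p = min(p, 1.0)
    haldane = any(x == 0 for x in (a, b, c, d))
    if haldane:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    odds = (aa * dd) / (bb * cc)
    return EnrichmentResult(
        table=((a, b), (c, d)), odds_ratio=float(odds), pvalue=p, haldane=haldane
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional batch correction; raw p by default upstream)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    q = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        q[i] = val
        prev = val
    return q


def snp_in_intervals(
    snps: Sequence[SnpRecord], intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean mask: SNP 0-based position inside any interval (half-open)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    arrays = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        arrays[chrom] = (
            np.array([s for s, _ in spans]),
            np.array([e for _, e in spans]),
        )
    mask = np.zeros(len(snps), dtype=bool)
    for i, snp in enumerate(snps):
        if snp.chrom not in arrays:
            continue
        starts, ends = arrays[snp.chrom]
        k = int(np.searchsorted(starts, snp.pos, side="right")) - 1
        mask[i] = k >= 0 and snp.pos < ends[k]
    return mask


def snp_feature_overlap(
    trait_snps: Sequence[SnpRecord],
    background_snps: Sequence[SnpRecord],
    feature_sets: dict[str, Sequence[GenomicInterval]],
) -> dict[str, EnrichmentResult]:
    """Per-feature Fisher enrichment of trait SNPs vs a background panel.

    A SNP is "in" a feature iff its 0-based position lies inside one of
    the feature's intervals.  The 2x2 table is (trait-in, trait-out) vs
    (background-in, background-out), tested one-sided for enrichment.
    """
    results: dict[str, EnrichmentResult] = {}
    for name, intervals in feature_sets.items():
        t_in = int(snp_in_intervals(trait_snps, intervals).sum())
        b_in = int(snp_in_intervals(background_snps, intervals).sum())
        res = fisher_exact(
            (
                (t_in, len(trait_snps) - t_in),
                (b_in, len(background_snps) - b_in),
            ),
            alternative="greater",
        )
        res.name = name
        results[name] = res
    return results


def _count_features_in_regions(
    feat_pos: dict[str, np.ndarray], regions: list[tuple[str, int, int]]
) -> int:
    total = 0
    for chrom, start, end in regions:
        pos = feat_pos.get(chrom)
        if pos is None:
            continue
        total += int(
            np.searchsorted(pos, end, side="left")
            - np.searchsorted(pos, start, side="left")
        )
    return total


def _feature_positions(features: Sequence[GenomicInterval | SnpRecord]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for f in features:
        if isinstance(f, SnpRecord):
            by_chrom.setdefault(f.chrom, []).append(f.pos)
        else:
            by_chrom.setdefault(f.chrom, []).append(f.midpoint)
    return {c: np.array(sorted(v)) for c, v in by_chrom.items()}


def permutation_enrichment(
    features: Sequence[GenomicInterval | SnpRecord],
    targets: Sequence[GenomicInterval],
    genome: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    max_rejection_rounds: int = 1000,
) -> PermutationResult:
    """Observed feature count in targets vs random length-matched regions.

    Each permutation draws ``len(targets)`` non-overlapping regions,
    length-matched 1:1 to the targets, uniformly over the genome with
    chromosomes weighted by length (rejection sampling, seeded).  Features
    are counted by position (SNPs) or midpoint (intervals).  The
    empirical p uses the add-one correction, so it is never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not targets:
        raise ValueError("no target regions supplied")
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    tlens = np.array([len(t) for t in targets], dtype=np.int64)
    if tlens.max() > lengths.max():
        raise ValueError("a target region is longer than every chromosome")
    weights = lengths / lengths.sum()
    feat_pos = _feature_positions(features)
    observed = _count_features_in_regions(
        feat_pos, [(t.chrom, t.start, t.end) for t in targets]
    )
    rng = np.random.default_rng(seed)
    reps = np.empty(n_perm, dtype=np.int64)
    for r in range(n_perm):
        for _attempt in range(max_rejection_rounds):
            ci = rng.choice(len(chroms), size=len(tlens), p=weights)
            # reject chromosomes shorter than the target length
            if np.any(lengths[ci] < tlens):
                continue
            starts = (rng.random(len(tlens)) * (lengths[ci] - tlens)).astype(np.int64)
            placed: dict[int, list[tuple[int, int]]] = {}
            ok = True
            for c, s, L in zip(ci, starts, tlens):
                spans = placed.setdefault(int(c), [])
                if any(s < e0 and s0 < s + L for s0, e0 in spans):
                    ok = False
                    break
                spans.append((int(s), int(s + L)))
            if ok:
                break
        else:
            raise RuntimeError(
                "could not place non-overlapping background regions after "
                f"{max_rejection_rounds} rejection rounds"
            )
        regions = [
            (chroms[c], s, e) for c, spans in placed.items() for s, e in spans
        ]
        reps[r] = _count_features_in_regions(feat_pos, regions)
    p = (1 + int(np.sum(reps >= observed))) / (1 + n_perm)
    return PermutationResult(
        observed=observed, replicates=reps, n_perm=n_perm, pvalue=p, seed=seed
    )


def allelic_imbalance(ref_count: int, alt_count: int) -> AlleleImbalanceResult:
    """Two-sided exact binomial test of allele read counts against 0.5.

    The p-value sums all outcomes whose probability does not exceed that
    of the observed count (the standard exact two-sided rule), so it is
    invariant under swapping ref and alt.
    """
    ref_count, alt_count = int(ref_count), int(alt_count)
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be non-negative")
    depth = ref_count + alt_count
    if depth == 0:
        raise ValueError("depth must be positive")
    p = binomtest(ref_count, depth, 0.5, alternative="two-sided").pvalue
    return AlleleImbalanceResult(
        ref_count=ref_count,
        alt_count=alt_count,
        depth=depth,
        ref_fraction=ref_count / depth,
        pvalue=float(min(p, 1.0)),
    )
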