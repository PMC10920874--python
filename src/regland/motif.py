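"""PWM log-odds scanning with exact p-value thresholds (FIMO-style).

Scores are log2 odds against a background base composition.  The null
distribution of scores under the background is computed exactly by
convolving the per-position score distributions on a discretized grid
(1e-3 bits), the same construction FIMO uses; thresholds and per-hit
p-values come from that distribution, never from empirical nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher

from .intervals import GenomicInterval, Peak

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in index space

#: Score-grid granularity in bits for the exact null distribution.
SCORE_GRANULARITY = 1e-3

#: Default pseudocount added to PWM probabilities before log-odds.
DEFAULT_PSEUDOCOUNT = 1e-3


@dataclass
class PWM:
    """A position probability matrix with background frequencies.

    ``matrix`` is width x 4 (A, C, G, T); each row sums to 1.  A
    pseudocount guards against zero probabilities before the log-odds
    transform.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """width x 4 matrix of log2((p + pc)/(1 + 4 pc) / bg)."""
        p = (self.matrix + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        return np.log2(p / self.background[None, :])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[COMPLEMENT].copy(),
            pseudocount=self.pseudocount,
        )

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.log_odds().min(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """A strand-aware scored motif occurrence."""

    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float
    pvalue: float
    threshold: float


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3; any other letter -> -1 (windows containing it are skipped)."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pwm_logodds_score(window: str, pwm: PWM) -> float:
    """Log2-odds score of a single window (length must equal PWM width)."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    codes = encode_sequence(window)
    if np.any(codes < 0):
        raise ValueError(f"non-ACGT base in window {window!r}")
    lod = pwm.log_odds()
    return float(lod[np.arange(pwm.width), codes].sum())


def _quantized_lod(pwm: PWM, granularity: float) -> np.ndarray:
    """Integer-grid log-odds matrix (width x 4)."""
    return np.rint(pwm.log_odds() / granularity).astype(np.int64)


_DIST_CACHE: dict[tuple, tuple[np.ndarray, int]] = {}


def score_distribution(
    pwm: PWM, granularity: float = SCORE_GRANULARITY
) -> tuple[np.ndarray, int]:
    """Exact null PMF of the quantized score under the background.

    Returns ``(pmf, offset)`` where ``pmf[k]`` is the probability that the
    integer score equals ``k + offset``.  Computed by exact convolution of
    the per-position distributions (each a 4-atom PMF, so the convolution
    is four shifted adds per position).  Cached per PWM.
    """
    if pwm.width > 25:
        raise ValueError("exact score distribution limited to width <= 25")
    key = (
        pwm.matrix.tobytes(),
        pwm.background.tobytes(),
        pwm.pseudocount,
        granularity,
    )
    cached = _DIST_CACHE.get(key)
    if cached is not None:
        return cached
    qlod = _quantized_lod(pwm, granularity)
    lo = int(qlod.min(axis=1).sum())
    hi = int(qlod.max(axis=1).sum())
    cur = np.zeros(int(qlod[0].max() - qlod[0].min()) + 1)
    base0 = int(qlod[0].min())
    for b in range(4):
        cur[qlod[0, b] - base0] += pwm.background[b]
    cur_offset = base0
    for i in range(1, pwm.width):
        base = int(qlod[i].min())
        span = int(qlod[i].max()) - base
        nxt = np.zeros(len(cur) + span)
        for b in range(4):
            sh = int(qlod[i, b]) - base
            nxt[sh : sh + len(cur)] += cur * pwm.background[b]
        cur = nxt
        cur_offset += base
    pmf = np.zeros(hi - lo + 1)
    pmf[cur_offset - lo : cur_offset - lo + len(cur)] = cur
    result = (pmf, lo)
    if len(_DIST_CACHE) > 256:
        _DIST_CACHE.clear()
    _DIST_CACHE[key] = result
    return result


_TAIL_CACHE: dict[tuple, tuple[np.ndarray, int]] = {}


def _tail_distribution(
    pwm: PWM, granularity: float = SCORE_GRANULARITY
) -> tuple[np.ndarray, int]:
    """Cached upper-tail (survival) array of the exact score distribution."""
    key = (pwm.matrix.tobytes(), pwm.background.tobytes(), pwm.pseudocount, granularity)
    cached = _TAIL_CACHE.get(key)
    if cached is None:
        pmf, offset = score_distribution(pwm, granularity)
        cached = (np.cumsum(pmf[::-1])[::-1], offset)
        if len(_TAIL_CACHE) > 256:
            _TAIL_CACHE.clear()
        _TAIL_CACHE[key] = cached
    return cached


def pwm_pvalue_threshold(
    pwm: PWM,
    p_target: float = 1e-4,
    granularity: float = SCORE_GRANULARITY,
) -> float:
    """Smallest score t with P(score >= t | background) <= p_target.

    Exact under the quantized score grid.  ``p_target=1`` returns the
    minimal attainable score.
    """
    if not (0.0 < p_target <= 1.0):
        raise ValueError("p_target must be in (0, 1]")
    pmf, offset = score_distribution(pwm, granularity)
    tail = np.cumsum(pmf[::-1])[::-1]
    # smallest index whose upper tail is <= p_target (1e-12 slop for the
    # float cumsum; p_target=1 must keep the minimal score)
    ok = tail <= p_target + 1e-12
    if not ok.any():
        # no attainable score is rare enough; place threshold above max
        return (offset + len(pmf)) * granularity
    idx = int(np.argmax(ok))
    return (offset + idx) * granularity


def score_tail_probability(
    pwm: PWM, score: float, granularity: float = SCORE_GRANULARITY
) -> float:
    """Exact P(score' >= score) under the background (quantized grid)."""
    pmf, offset = score_distribution(pwm, granularity)
    k = int(np.rint(score / granularity)) - offset
    if k <= 0:
        return 1.0
    if k >= len(pmf):
        return 0.0
    return float(pmf[k:].sum())


def scan_sequence(
    seq: str,
    pwm: PWM,
    threshold: float,
    chrom: str = "seq",
    offset: int = 0,
    granularity: float = SCORE_GRANULARITY,
) -> list[MotifHit]:
    """Scan both strands; hits sorted by position (overlaps retained).

    Scores and the threshold are compared on the quantized grid so that a
    threshold produced by :func:`pwm_pvalue_threshold` admits exactly the
    scores whose exact tail probability meets the target.  Windows with
    non-ACGT bases are skipped.
    """
    w = pwm.width
    codes = encode_sequence(seq)
    if len(codes) < w:
        return []
    tail, pmf_offset = _tail_distribution(pwm, granularity)
    t_int = int(np.rint(threshold / granularity))

    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = ~(windows < 0).any(axis=1)
    hits: list[tuple[int, str, int]] = []  # (start, strand, int score)
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        qlod = _quantized_lod(mat, granularity)
        # pad a row for invalid (-1) codes, scored 0 then masked
        padded = np.vstack([qlod.T, np.zeros((1, w), dtype=np.int64)])  # 5 x w
        scores = padded[windows, np.arange(w)].sum(axis=1)
        sel = np.flatnonzero(valid & (scores >= t_int))
        hits.extend((int(s), strand, int(scores[s])) for s in sel)
    hits.sort(key=lambda h: (h[0], h[1]))
    out = []
    for start, strand, q in hits:
        k = q - pmf_offset
        pval = float(tail[min(k, len(tail) - 1)]) if k >= 0 else 1.0
        out.append(
            MotifHit(
                motif_id=pwm.name,
                interval=GenomicInterval(chrom, offset + start, offset + start + w, strand),
                strand=strand,
                score=q * granularity,
                pvalue=pval,
                threshold=t_int * granularity,
            )
        )
    return out


def scan_genome(
    genome: dict[str, str],
    pwms: Sequence[PWM],
    p_target: float = 1e-4,
    regions: Optional[Sequence[GenomicInterval]] = None,
) -> list[MotifHit]:
    """Scan whole chromosomes, or only ``regions``, with per-PWM thresholds."""
    hits: list[MotifHit] = []
    for pwm in pwms:
        thr = pwm_pvalue_threshold(pwm, p_target)
        if regions is None:
            for chrom, seq in genome.items():
                hits.extend(scan_sequence(seq, pwm, thr, chrom=chrom))
        else:
            for iv in regions:
                seq = genome[iv.chrom][iv.start : iv.end]
                hits.extend(scan_sequence(seq, pwm, thr, chrom=iv.chrom, offset=iv.start))
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.motif_id, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Control sequences and enrichment


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erikson).

    Builds a random Eulerian path on the 4-letter transition multigraph so
    the shuffled sequence has the same first-order composition as the
    input.  Sequences shorter than 3 letters are returned unchanged.
    """
    if len(seq) < 3:
        return seq
    letters = sorted(set(seq))
    edges: dict[str, list[str]] = {a: [] for a in letters}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    # Pick, for each vertex except the terminal one, a random final edge such
    # that the final-edge graph is connected to the terminal vertex.
    for _ in range(2000):
        final: dict[str, str] = {}
        for a in letters:
            if a == last or not edges[a]:
                continue
            final[a] = edges[a][rng.integers(len(edges[a]))]
        # check: following final edges from each vertex reaches `last`
        ok = True
        for a in final:
            seen = {a}
            cur = a
            while cur != last:
                cur = final.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - cannot happen for valid inputs
        raise RuntimeError("dinucleotide shuffle failed to converge")
    shuffled_edges: dict[str, list[str]] = {}
    for a in letters:
        rest = list(edges[a])
        if a in final:
            rest.remove(final[a])
        perm = rng.permutation(len(rest))
        shuffled_edges[a] = [rest[i] for i in perm] + ([final[a]] if a in final else [])
    out = [seq[0]]
    counters = {a: 0 for a in letters}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def motif_enrichment_in_regions(
    region_seqs: Sequence[str],
    pwms: Sequence[PWM],
    seed: int,
    p_target: float = 1e-4,
):
    """Per-motif enrichment of hits in regions vs dinucleotide shuffles.

    Controls are one dinucleotide-preserving shuffle per region (seeded).
    The statistic is the one-sided Fisher p on (regions with >= 1 hit) vs
    (controls with >= 1 hit).  Callers are expected to pre-filter ``pwms``
    to expressed TFs (the TPM > 50 rule).
    """
    from .stats import EnrichmentResult, fisher_exact

    if not region_seqs:
        raise ValueError("no regions supplied")
    rng = np.random.default_rng(seed)
    controls = [dinucleotide_shuffle(s, rng) for s in region_seqs]
    results: list[EnrichmentResult] = []
    for pwm in pwms:
        thr = pwm_pvalue_threshold(pwm, p_target)
        n_reg = sum(bool(scan_sequence(s, pwm, thr)) for s in region_seqs)
        n_ctl = sum(bool(scan_sequence(s, pwm, thr)) for s in controls)
        table = (
            (n_reg, len(region_seqs) - n_reg),
            (n_ctl, len(controls) - n_ctl),
        )
        res = fisher_exact(table, alternative="greater")
        res.name = pwm.name
        results.append(res)
    results.sort(key=lambda r: (r.pvalue, r.name))
    return results


def colocalization_by_position(
    anchor_peaks: Sequence[Peak],
    hits_by_peak: Sequence[Sequence[MotifHit]],
    classification: Sequence[str],
    anchor_motif: Optional[str] = None,
    partner_motif: Optional[str] = None,
):
    """Proximal/distal motif occurrence 2x2 tests plus spacing distribution.

    ``classification[i]`` must be "proximal" or "distal" for every anchor
    peak.  For peaks containing both ``anchor_motif`` and
    ``partner_motif`` hits, the start-to-start distances between the
    nearest pairs are returned as the spacing distribution.
    """
    from .stats import fisher_exact

    if len(anchor_peaks) != len(hits_by_peak) or len(anchor_peaks) != len(classification):
        raise ValueError("peaks, hits and classification must align")
    for i, c in enumerate(classification):
        if c not in ("proximal", "distal"):
            raise ValueError(f"peak {i}: classification must be proximal/distal, got {c!r}")
    motifs = sorted({h.motif_id for hits in hits_by_peak for h in hits})
    tables = {}
    for m in motifs:
        has = [any(h.motif_id == m for h in hits) for hits in hits_by_peak]
        dp = sum(1 for h, c in zip(has, classification) if h and c == "distal")
        dn = sum(1 for h, c in zip(has, classification) if not h and c == "distal")
        pp = sum(1 for h, c in zip(has, classification) if h and c == "proximal")
        pn = sum(1 for h, c in zip(has, classification) if not h and c == "proximal")
        res = fisher_exact(((dp, dn), (pp, pn)), alternative="greater")
        res.name = m
        tables[m] = res
    spacings: list[int] = []
    if anchor_motif is not None and partner_motif is not None:
        for hits in hits_by_peak:
            a_starts = [h.interval.start for h in hits if h.motif_id == anchor_motif]
            p_starts = [h.interval.start for h in hits if h.motif_id == partner_motif]
            for a in a_starts:
                if p_starts:
                    spacings.append(min((abs(p - a) for p in p_starts)))
    return tables, spacings


def allele_score_delta(
    pwm: PWM, ref_window: str, alt_window: str
) -> float:
    """Descriptive ref-vs-alt binding-score change (alt minus ref, bits)."""
    return pwm_logodds_score(alt_window, pwm) - pwm_logodds_score(ref_window, pwm)
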