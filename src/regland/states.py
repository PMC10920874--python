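"""Chromatin-state segmentations (consumed, never trained, by this package)."""

from __future__ import annotations

from typing import Iterable

import numpy as np

#: The 18-state Roadmap expanded-model mnemonics, in legend order.  The order
#: doubles as the deterministic tie-break when a peak overlaps two states
#: equally.
ROADMAP_18_STATES = [
    "TssA",
    "TssFlnk",
    "TssFlnkU",
    "TssFlnkD",
    "Tx",
    "TxWk",
    "EnhG1",
    "EnhG2",
    "EnhA1",
    "EnhA2",
    "EnhWk",
    "ZNF/Rpts",
    "Het",
    "TssBiv",
    "EnhBiv",
    "ReprPC",
    "ReprPCWk",
    "Quies",
]

#: States treated as "active" (promoter or enhancer) in summaries.
ACTIVE_STATES = {"TssA", "TssFlnk", "TssFlnkU", "TssFlnkD", "EnhA1", "EnhA2"}


class StateSegmentation:
    """Per-tissue labeled tiling of the genome by chromatin state.

    Segments must tile each chromosome without overlap; labels must come
    from the declared vocabulary.
    """

    def __init__(
        self,
        tissue: str,
        segments: Iterable[tuple[str, int, int, str]],
        vocabulary: list[str] | None = None,
    ) -> None:
        self.tissue = tissue
        self.vocabulary = list(vocabulary) if vocabulary is not None else list(ROADMAP_18_STATES)
        vocab_set = set(self.vocabulary)
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, state in segments:
            if end <= start:
                raise ValueError(f"empty segment [{start},{end}) on {chrom}")
            if state not in vocab_set:
                raise ValueError(f"unknown state mnemonic {state!r}")
            by_chrom.setdefault(chrom, []).append((start, end, state))
        self._segments: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        for chrom, segs in by_chrom.items():
            segs.sort()
            starts = np.array([s[0] for s in segs], dtype=np.int64)
            ends = np.array([s[1] for s in segs], dtype=np.int64)
            states = [s[2] for s in segs]
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping segments on {chrom}")
            self._segments[chrom] = (starts, ends, states)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._segments)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._segments

    def iter_segments(self) -> Iterable[tuple[str, int, int, str]]:
        for chrom in self.chroms:
            starts, ends, states = self._segments[chrom]
            for s, e, st in zip(starts, ends, states):
                yield chrom, int(s), int(e), st

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, str]]:
        """Segments intersecting [start, end), clipped to the query."""
        if chrom not in self._segments:
            raise KeyError(f"chromosome {chrom!r} absent from segmentation")
        starts, ends, states = self._segments[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return [
            (max(int(starts[k]), start), min(int(ends[k]), end), states[k])
            for k in range(lo, hi)
        ]

    def state_bp(self) -> dict[str, int]:
        """Total bp covered by each state across all chromosomes."""
        totals: dict[str, int] = {}
        for chrom in self._segments:
            starts, ends, states = self._segments[chrom]
            for s, e, st in zip(starts, ends, states):
                totals[st] = totals.get(st, 0) + int(e - s)
        return totals
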