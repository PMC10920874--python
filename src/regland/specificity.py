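"""Tissue specificity of genes and regulatory elements, element-to-gene
assignment, and the three-criterion identity-gene screen.

A gene is expression-specific when its focal-tissue TPM standardized
against the across-tissue mean and sample SD (focal included) exceeds
z_min and the focal TPM exceeds tpm_min (defaults 7 and 50).  An
identity gene must additionally be linked to a tissue-specific enhancer
or super-enhancer and be bound by the master TF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, LoopRecord, Peak, interval_overlap
from .superenhancer import cross_tissue_se_specificity


@dataclass
class SpecificityResult:
    gene_id: str
    tpm_focal: float
    z: float
    specific: bool


@dataclass
class ElementLink:
    """An element -> gene association with its evidence channel."""

    element: GenomicInterval
    gene_id: str
    evidence: str  # "nearest" or "loop"
    distance: Optional[int] = None


@dataclass
class IdentityGeneRecord:
    gene_id: str
    has_specific_element: bool
    is_expression_specific: bool
    is_tf_target: bool
    z: float = float("nan")

    @property
    def passes(self) -> bool:
        return self.has_specific_element and self.is_expression_specific and self.is_tf_target


def expression_zscores(
    expr: pd.DataFrame,
    focal: str,
    z_min: float = 7.0,
    tpm_min: float = 50.0,
) -> list[SpecificityResult]:
    """Per-gene focal-tissue z-scores across tissues (genes x tissues TPM).

    z = (TPM_focal - mean over tissues) / sample SD (ddof=1, focal
    included); genes with zero SD get z = 0 and are never specific.
    """
    if focal not in expr.columns:
        raise KeyError(f"focal tissue {focal!r} absent from expression matrix")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 tissues for z-scores")
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    focal_vals = expr[focal].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (focal_vals - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    out = []
    for gene, zi, tpm in zip(expr.index, z, focal_vals):
        out.append(
            SpecificityResult(
                gene_id=str(gene),
                tpm_focal=float(tpm),
                z=float(zi),
                specific=bool(zi > z_min and tpm > tpm_min),
            )
        )
    return out


def tissue_specific_elements(
    element_sets: dict[str, Sequence[GenomicInterval]],
    focal: str,
    min_overlap_fraction: float = 0.25,
) -> dict[GenomicInterval, bool]:
    """Specificity of focal elements across tissues.

    Same sharing rule as super-enhancer specificity: a focal element is
    specific iff it appears (>= min_overlap_fraction reciprocal overlap
    of the focal element) in no more than one other tissue.
    """
    return cross_tissue_se_specificity(element_sets, focal, min_overlap_fraction)


def assign_elements_to_genes(
    elements: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    loops: Optional[Sequence[LoopRecord]] = None,
    max_distance: int = 500_000,
    loop_tss_window: int = 5000,
) -> list[ElementLink]:
    """Element -> gene links by nearest TSS and (optionally) loops.

    Default rule: each element links to the gene with the nearest TSS
    (from the element midpoint) within ``max_distance``.  When loops are
    supplied, an additional link is made whenever one anchor overlaps the
    element and the other overlaps +/- ``loop_tss_window`` of a TSS.
    """
    if not gene_models:
        raise ValueError("gene models must be non-empty")
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in gene_models:
        tss_by_chrom.setdefault(g.interval.chrom, []).append((g.tss, g.gene_id))
    for c in tss_by_chrom:
        tss_by_chrom[c].sort()
    links: list[ElementLink] = []
    for el in elements:
        entries = tss_by_chrom.get(el.chrom, [])
        if entries:
            arr = np.array([t for t, _ in entries])
            mid = el.midpoint
            k = int(np.searchsorted(arr, mid))
            best = None
            for j in (k - 1, k):
                if 0 <= j < arr.size:
                    d = abs(int(arr[j]) - mid)
                    if best is None or d < best[0]:
                        best = (d, entries[j][1])
            if best is not None and best[0] <= max_distance:
                links.append(
                    ElementLink(element=el, gene_id=best[1], evidence="nearest", distance=best[0])
                )
    if loops:
        tss_windows = []
        gene_ids = []
        for g in gene_models:
            start = max(0, g.tss - loop_tss_window)
            tss_windows.append(GenomicInterval(g.interval.chrom, start, g.tss + loop_tss_window + 1))
            gene_ids.append(g.gene_id)
        existing = {(l.element, l.gene_id, l.evidence) for l in links}
        for lp in loops:
            for el_anchor, tss_anchor in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
                el_hits = [el for el in elements if el.overlaps(el_anchor)]
                if not el_hits:
                    continue
                for w, gid in zip(tss_windows, gene_ids):
                    if w.overlaps(tss_anchor):
                        for el in el_hits:
                            key = (el, gid, "loop")
                            if key not in existing:
                                existing.add(key)
                                links.append(
                                    ElementLink(element=el, gene_id=gid, evidence="loop")
                                )
    return links


def identity_gene_screen(
    spec_results: Sequence[SpecificityResult],
    specific_element_links: Sequence[ElementLink],
    tf_peaks: Sequence[Peak],
    gene_models: Sequence[GeneModel],
) -> list[IdentityGeneRecord]:
    """Integrate expression, specific elements, and master-TF binding.

    A gene passes when it (1) is linked to a tissue-specific enhancer or
    super-enhancer, (2) is expression-specific, and (3) has a TF peak
    overlapping its gene body or one of its linked elements.  Output is
    sorted by z descending.
    """
    genes = {g.gene_id: g for g in gene_models}
    links_by_gene: dict[str, list[ElementLink]] = {}
    for link in specific_element_links:
        links_by_gene.setdefault(link.gene_id, []).append(link)
    tf_ivs = [p.interval for p in tf_peaks]
    records = []
    for sr in spec_results:
        g = genes.get(sr.gene_id)
        if g is None:
            continue
        gene_links = links_by_gene.get(sr.gene_id, [])
        has_element = bool(gene_links)
        targets = [g.interval] + [l.element for l in gene_links]
        is_target = bool(interval_overlap(targets, tf_ivs))
        records.append(
            IdentityGeneRecord(
                gene_id=sr.gene_id,
                has_specific_element=has_element,
                is_expression_specific=sr.specific,
                is_tf_target=is_target,
                z=sr.z,
            )
        )
    records.sort(key=lambda r: (-r.z, r.gene_id))
    return records
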