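"""Master-TF-centered core regulatory circuit reconstruction.

Nodes are transcription factors that are expressed (TPM above threshold)
and super-enhancer-associated; a directed edge A -> B means a motif of A
occurs inside a DNase hypersensitive site within +/- 5 kb of B's TSS.
Autoregulation is a self-edge; connectivity is in-degree + out-degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .intervals import GeneModel, GenomicInterval, interval_overlap
from .motif import MotifHit


@dataclass
class CircuitNode:
    tf: str
    tpm: float
    has_se: bool

    @property
    def autoregulated(self) -> bool:  # set by the graph
        return getattr(self, "_auto", False)


@dataclass
class CircuitGraph:
    """Directed TF -> TF graph with autoregulation and connectivity."""

    nodes: dict[str, CircuitNode]
    edges: list[tuple[str, str]]  # sorted, deterministic

    def out_degree(self, tf: str) -> int:
        return sum(1 for a, _ in self.edges if a == tf)

    def in_degree(self, tf: str) -> int:
        return sum(1 for _, b in self.edges if b == tf)

    def connectivity(self, tf: str) -> int:
        return self.in_degree(tf) + self.out_degree(tf)

    def is_autoregulated(self, tf: str) -> bool:
        return (tf, tf) in set(self.edges)

    def to_edge_table(self) -> str:
        lines = ["source\ttarget"]
        lines += [f"{a}\t{b}" for a, b in self.edges]
        return "\n".join(lines) + "\n"

    def to_node_table(self) -> str:
        lines = ["tf\ttpm\thas_se\tautoregulated\tconnectivity"]
        for tf in sorted(self.nodes):
            n = self.nodes[tf]
            lines.append(
                f"{tf}\t{n.tpm:.6g}\t{int(n.has_se)}\t{int(self.is_autoregulated(tf))}"
                f"\t{self.connectivity(tf)}"
            )
        return "\n".join(lines) + "\n"


def find_regulators(
    target_gene: GeneModel,
    dhs: Sequence[GenomicInterval],
    motif_hits: Sequence[MotifHit],
    motif_to_tf: dict[str, str],
    window: int = 5000,
) -> set[str]:
    """TFs with >= 1 motif hit inside a DHS overlapping TSS +/- window."""
    tss = target_gene.tss
    win = GenomicInterval(
        target_gene.interval.chrom, max(0, tss - window), tss + window + 1
    )
    window_dhs = [d for d in dhs if d.overlaps(win)]
    if not window_dhs:
        return set()
    regulators: set[str] = set()
    hit_ivs = [h.interval for h in motif_hits]
    for hi, _di in interval_overlap(hit_ivs, window_dhs):
        h = motif_hits[hi]
        # a hit counts only if fully inside the DHS? >=1 bp overlap with an
        # open-chromatin site suffices; the DHS must itself touch the window
        tf = motif_to_tf.get(h.motif_id)
        if tf is not None:
            regulators.add(tf)
    return regulators


def build_circuit(
    seed_tf: str,
    candidate_tfs: Sequence[str],
    expr_tpm: dict[str, float],
    se_membership: dict[str, bool],
    dhs: Sequence[GenomicInterval],
    motif_hits: Sequence[MotifHit],
    motif_to_tf: dict[str, str],
    gene_models: Sequence[GeneModel],
    tpm_min: float = 50.0,
    window: int = 5000,
) -> CircuitGraph:
    """Construct the circuit over candidates passing both node filters.

    Candidates must be expressed (TPM > tpm_min) and super-enhancer
    associated; the seed TF failing either filter is a configuration
    error.  Edges come from :func:`find_regulators` applied to every
    node's gene model; ordering is deterministic.
    """
    if seed_tf not in candidate_tfs:
        raise ValueError(f"seed TF {seed_tf!r} not among candidates")
    genes = {g.gene_id: g for g in gene_models}

    def passes(tf: str) -> bool:
        return expr_tpm.get(tf, 0.0) > tpm_min and se_membership.get(tf, False)

    if not passes(seed_tf):
        raise ValueError(
            f"seed TF {seed_tf!r} fails the expression/SE node filter "
            f"(TPM={expr_tpm.get(seed_tf, 0.0)}, SE={se_membership.get(seed_tf, False)})"
        )
    members = sorted(tf for tf in candidate_tfs if passes(tf))
    nodes = {
        tf: CircuitNode(tf=tf, tpm=expr_tpm[tf], has_se=True) for tf in members
    }
    member_set = set(members)
    edges: set[tuple[str, str]] = set()
    for target in members:
        g = genes.get(target)
        if g is None:
            raise KeyError(f"TF {target!r} has no gene model")
        for regulator in find_regulators(g, dhs, motif_hits, motif_to_tf, window=window):
            if regulator in member_set:
                edges.add((regulator, target))
    return CircuitGraph(nodes=nodes, edges=sorted(edges))


def connectivity_ranking(graph: CircuitGraph) -> list[tuple[str, int]]:
    """TFs sorted by in+out degree descending; ties by TF id."""
    ranked = [(tf, graph.connectivity(tf)) for tf in graph.nodes]
    ranked.sort(key=lambda x: (-x[1], x[0]))
    return ranked


def top_of_hierarchy(
    graph: CircuitGraph, max_regulators: int = 1
) -> dict[str, list[str]]:
    """Apex TFs: out-degree > 0, regulated by <= k distinct non-self TFs.

    Self-edges are excluded from the in-count.  Returns each apex TF with
    its (possibly empty) regulator list.
    """
    out: dict[str, list[str]] = {}
    for tf in sorted(graph.nodes):
        regulators = sorted({a for a, b in graph.edges if b == tf and a != tf})
        out_degree = sum(1 for a, b in graph.edges if a == tf and b != tf)
        if out_degree > 0 and len(regulators) <= max_regulators:
            out[tf] = regulators
    return out
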