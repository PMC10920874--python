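"""Seeded generator of a miniature multi-tissue regulatory landscape.

The bundle emulates the statistical structure the analysis assumes —
H3K27ac-dense super-enhancers over a low gamma-noise background, TF
peaks carrying exact consensus plantings of a synthetic PWM battery,
open-chromatin sites wired into a known TF->TF circuit, a tissue
expression matrix with genes planted to exceed the z > 7 / TPM > 50
specificity rule, SNP panels concentrated inside super-enhancers, and
binomially imbalanced allele counts — and writes every input file the
pipeline consumes plus a ground-truth manifest (JSON).

Planted truth is exact by construction: after planting, the background
sequence of every DHS is rejection-resampled until the emitted PWM
battery (at the FIMO-style p = 1e-4 threshold) has no occurrences there
other than the planted ones, so circuit edges recovered downstream are
the planted adjacency, not an approximation of it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as rio
from .intervals import GeneModel, GenomicInterval, LoopRecord, Peak, SignalTrack, SnpRecord
from .motif import BASES, PWM, pwm_pvalue_threshold, scan_sequence
from .states import StateSegmentation

FOCAL_TISSUE = "parathyroid"
OTHER_TISSUES = ["liver", "lung", "heart", "kidney", "brain"]

_RUN = 200  # signal-run and layout grid, bp


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic bundle.

    Defaults are the conditions the downstream suites run under: a
    2 x 1 Mb genome, 6 chromatin tissues (one focal), a 55-tissue
    expression panel (the focal-included z-score is bounded by
    (n-1)/sqrt(n), so z > 7 planting needs ~50+ tissues), 8 circuit TFs
    plus 2 filter-decoy TFs, and super-enhancers at 10x background over
    >= 10 kb versus ordinary enhancers at ~2x.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_tissues: int = 6
    n_expression_tissues: int = 55
    n_genes: int = 100
    n_tf_motifs: int = 8
    n_identity_se_genes: int = 5
    n_identity_enh_genes: int = 3
    n_specific_only_genes: int = 3
    n_se_per_other_tissue: int = 5
    n_typical_enhancers: int = 20
    n_loops: int = 3
    extra_edge_density: float = 0.25
    n_enriched_snps: int = 100
    n_control_snps: int = 300
    snp_se_fraction: float = 0.8
    n_het_sites: int = 20
    imbalance_fraction: float = 0.67
    imbalanced_site_fraction: float = 0.5
    allele_depth_mean: float = 88.0
    background_mean: float = 1.0
    se_amplitude: float = 10.0
    enhancer_amplitude: float = 2.0
    motif_consensus_prob: float = 0.97
    motif_p_target: float = 1e-4
    z_min: float = 7.0
    tpm_min: float = 50.0

    @property
    def tissues(self) -> list[str]:
        return [FOCAL_TISSUE] + OTHER_TISSUES[: self.n_tissues - 1]

    @property
    def n_candidate_tfs(self) -> int:
        return self.n_tf_motifs + 2  # + low-TPM decoy and no-SE decoy

    def validate(self) -> None:
        errors = []
        for name in (
            "n_chroms",
            "chrom_length",
            "n_tissues",
            "n_expression_tissues",
            "n_genes",
            "n_tf_motifs",
            "n_identity_se_genes",
            "n_identity_enh_genes",
            "n_se_per_other_tissue",
            "n_typical_enhancers",
            "n_enriched_snps",
            "n_control_snps",
            "n_het_sites",
        ):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if not (2 <= self.n_tissues <= 1 + len(OTHER_TISSUES)):
            errors.append(f"n_tissues must be in [2, {1 + len(OTHER_TISSUES)}]")
        if self.n_tf_motifs < 6:
            errors.append("n_tf_motifs must be >= 6 (structural circuit planting)")
        n = self.n_expression_tissues
        if n >= 3 and (n - 1) / np.sqrt(n) <= self.z_min:
            errors.append(
                f"z > {self.z_min} is unattainable with {n} expression tissues "
                f"(focal-included z is bounded by (n-1)/sqrt(n) = {(n - 1) / np.sqrt(n):.2f})"
            )
        if not (0.0 < self.snp_se_fraction <= 1.0):
            errors.append("snp_se_fraction must be in (0, 1]")
        if not (0.0 < self.imbalance_fraction < 1.0):
            errors.append("imbalance_fraction must be in (0, 1)")
        if self.n_genes < self._n_special_genes():
            errors.append(
                f"n_genes={self.n_genes} smaller than the {self._n_special_genes()} "
                "planted special genes"
            )
        if errors:
            raise ValueError("invalid simulation config: " + "; ".join(errors))

    def _n_special_genes(self) -> int:
        # TFs + identity genes + 3 decoys + plain specific genes
        return (
            self.n_candidate_tfs
            + self.n_identity_se_genes
            + self.n_identity_enh_genes
            + 3
            + self.n_specific_only_genes
        )


@dataclass
class TruthManifest:
    """Ground truth of one emitted bundle (also serialized as manifest.json)."""

    config: dict
    tissues: list[str]
    focal: str
    se_intervals: dict[str, list[list]]
    specific_genes: list[str]
    identity_genes: list[str]
    decoys: dict[str, str]
    circuit_tfs: list[str]
    seed_tf: str
    apex_tf: str
    circuit_edges: list[list[str]]
    motif_occurrences: list[dict]
    enriched_snps: list[dict]
    allele_truth: dict[str, float]
    loops: list[dict]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path) -> "TruthManifest":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# layout bookkeeping


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    tss: int
    start: int
    end: int
    strand: str = "+"
    role: str = "filler"


class _Layout:
    """Sequential cassette placement on the 200 bp grid."""

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
        self.chrom_idx = 0
        self.cursor = 1000

    def alloc(self, size: int, gap: int) -> tuple[str, int]:
        total = size + gap
        while self.cursor + total > self.cfg.chrom_length - 1000:
            self.chrom_idx += 1
            self.cursor = 1000
            if self.chrom_idx >= len(self.chroms):
                raise ValueError(
                    "infeasible planting: requested features exceed genome capacity "
                    f"({self.cfg.n_chroms} x {self.cfg.chrom_length} bp)"
                )
        chrom = self.chroms[self.chrom_idx]
        start = self.cursor
        self.cursor = -(-(self.cursor + total) // _RUN) * _RUN  # round up to grid
        return chrom, start


_SE_PEAK_OFFSETS = [(0, 2600), (3200, 5800), (6400, 9000), (9400, 12000)]
_SE_LENGTH = 12000


def _make_pwms(cfg: SimulationConfig, rng: np.random.Generator) -> list[PWM]:
    pwms = []
    for k in range(cfg.n_candidate_tfs):
        w = int(rng.integers(8, 13))
        consensus = rng.integers(0, 4, size=w)
        mat = np.full((w, 4), (1.0 - cfg.motif_consensus_prob) / 3.0)
        mat[np.arange(w), consensus] = cfg.motif_consensus_prob
        pwms.append(PWM(name=f"M_TF{k}", matrix=mat))
    return pwms


def simulate(config: SimulationConfig, outdir) -> TruthManifest:
    """Emit the full file bundle into ``outdir`` and return the truth manifest.

    Identical config + seed produce a byte-identical bundle.
    """
    cfg = config
    cfg.validate()
    outdir = Path(outdir)

    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_pwm = np.random.default_rng(streams[0])
    rng_adj = np.random.default_rng(streams[1])
    rng_genome = np.random.default_rng(streams[2])
    rng_bg = np.random.default_rng(streams[3])
    rng_expr = np.random.default_rng(streams[4])
    rng_snp = np.random.default_rng(streams[5])
    rng_allele = np.random.default_rng(streams[6])
    rng_clean = np.random.default_rng(streams[7])

    tf_names = [f"TF{k}" for k in range(cfg.n_candidate_tfs)]
    core_tfs = tf_names[: cfg.n_tf_motifs]
    tf_low, tf_nose = tf_names[cfg.n_tf_motifs], tf_names[cfg.n_tf_motifs + 1]
    seed_tf, apex_tf = core_tfs[0], core_tfs[1]
    pwms = _make_pwms(cfg, rng_pwm)
    pwm_by_tf = {tf: pwm for tf, pwm in zip(tf_names, pwms)}

    # planted adjacency over the core TFs
    edges: set[tuple[str, str]] = set()
    edges.add((seed_tf, seed_tf))  # master autoregulation
    for tgt in core_tfs[2:5]:
        edges.add((seed_tf, tgt))
    edges.add((apex_tf, apex_tf))
    for tgt in (core_tfs[0], core_tfs[2], core_tfs[4], core_tfs[5 % len(core_tfs)]):
        if tgt != apex_tf:
            edges.add((apex_tf, tgt))
    for a in core_tfs[2:]:
        for b in core_tfs:
            if b == apex_tf:
                continue  # keep the apex unregulated by others
            if rng_adj.random() < cfg.extra_edge_density:
                edges.add((a, b))
    adjacency = sorted(edges)

    # ----- layout ------------------------------------------------------
    layout = _Layout(cfg)
    genes: list[_Gene] = []
    dhs: list[tuple[GenomicInterval, str]] = []  # (interval, kind)
    h3k_peaks: list[tuple[GenomicInterval, float, str]] = []  # (iv, amplitude x bg, name)
    master_peaks: list[GenomicInterval] = []
    focal_se: list[dict] = []  # interval, gene, kind, shared_with
    promoter_sites: list[tuple[str, GenomicInterval]] = []  # (tf gene, promoter DHS)

    def add_se(chrom: str, start: int, gene_id: str, kind: str, with_master: bool) -> dict:
        iv = GenomicInterval(chrom, start, start + _SE_LENGTH)
        for j, (o1, o2) in enumerate(_SE_PEAK_OFFSETS):
            piv = GenomicInterval(chrom, start + o1, start + o2)
            h3k_peaks.append((piv, cfg.se_amplitude, f"{gene_id}_se_p{j}"))
            dhs.append((piv, "se"))
            if with_master and j < 2:
                master_peaks.append(GenomicInterval(chrom, piv.start + 100, piv.start + 500))
        rec = {"interval": iv, "gene": gene_id, "kind": kind, "shared_with": []}
        focal_se.append(rec)
        return rec

    # TF cassettes (core TFs + low-TPM decoy get SEs; no-SE decoy is plain)
    for tf in tf_names:
        has_se = tf != tf_nose
        size = 18200 if has_se else 2400
        chrom, c0 = layout.alloc(size, gap=13000 if has_se else 3000)
        tss = c0 + 200
        genes.append(_Gene(tf, chrom, tss, tss, tss + 2000, "+", role="tf"))
        prom = GenomicInterval(chrom, c0 + 100, c0 + 400)
        dhs.append((prom, "promoter"))
        promoter_sites.append((tf, prom))
        if has_se:
            rec = add_se(chrom, tss + 6000, tf, "tf_se", with_master=False)
            if tf == core_tfs[2]:
                rec["shared_with"] = [OTHER_TISSUES[0]]
            if tf == core_tfs[3]:
                rec["shared_with"] = OTHER_TISSUES[:2]

    # identity genes with SEs, plus SE-bearing decoys
    idg_se = [f"IDG_SE{i}" for i in range(cfg.n_identity_se_genes)]
    for gid in idg_se:
        chrom, c0 = layout.alloc(16000, gap=13000)
        genes.append(_Gene(gid, chrom, c0, c0, c0 + 2000, "+", role="identity_se"))
        add_se(chrom, c0 + 4000, gid, "identity_se", with_master=True)
    for gid, kind, with_master in (
        ("DEC_SE_LOWEXPR", "decoy_se_lowexpr", True),
        ("DEC_SE_NOTF", "decoy_se_notf", False),
    ):
        chrom, c0 = layout.alloc(16000, gap=13000)
        genes.append(_Gene(gid, chrom, c0, c0, c0 + 2000, "+", role=kind))
        add_se(chrom, c0 + 4000, gid, kind, with_master=with_master)

    # identity genes with specific typical enhancers
    idg_enh = [f"IDG_ENH{i}" for i in range(cfg.n_identity_enh_genes)]
    enh_elements: list[tuple[GenomicInterval, str]] = []  # (iv, gene)
    for gid in idg_enh:
        chrom, c0 = layout.alloc(3600, gap=13000)
        genes.append(_Gene(gid, chrom, c0, c0, c0 + 2000, "+", role="identity_enh"))
        iv = GenomicInterval(chrom, c0 + 3000, c0 + 3600)
        h3k_peaks.append((iv, cfg.enhancer_amplitude, f"{gid}_enh"))
        dhs.append((iv, "enhancer"))
        enh_elements.append((iv, gid))
        master_peaks.append(GenomicInterval(chrom, iv.start + 100, iv.start + 500))

    # other-tissue SE slots
    other_se: dict[str, list[GenomicInterval]] = {t: [] for t in cfg.tissues[1:]}
    for t in cfg.tissues[1:]:
        for _ in range(cfg.n_se_per_other_tissue):
            chrom, c0 = layout.alloc(_SE_LENGTH, gap=1000)
            other_se[t].append(GenomicInterval(chrom, c0, c0 + _SE_LENGTH))
    for rec in focal_se:
        for t in rec["shared_with"]:
            other_se[t].append(rec["interval"])

    # typical enhancers (focal-specific, low amplitude)
    typical: list[GenomicInterval] = []
    for i in range(cfg.n_typical_enhancers):
        chrom, c0 = layout.alloc(600, gap=13000)
        iv = GenomicInterval(chrom, c0, c0 + 600)
        typical.append(iv)
        h3k_peaks.append((iv, cfg.enhancer_amplitude, f"typ_enh{i}"))
        dhs.append((iv, "enhancer"))
        if i < 5:
            master_peaks.append(GenomicInterval(chrom, c0 + 100, c0 + 500))

    # plain specific genes and the no-element expression decoy
    spec_plain = [f"SPEC{i}" for i in range(cfg.n_specific_only_genes)] + ["DEC_EXPR_NOEL"]
    n_fillers = cfg.n_genes - len(genes) - len(spec_plain)
    filler_ids = [f"G{i:03d}" for i in range(n_fillers)]
    # fillers flank the specific-only genes so no specific element is nearest
    order = (
        filler_ids[: n_fillers // 2]
        + spec_plain
        + filler_ids[n_fillers // 2 :]
    )
    for gid in order:
        chrom, c0 = layout.alloc(2000, gap=1000)
        role = "specific_plain" if gid in spec_plain else "filler"
        genes.append(_Gene(gid, chrom, c0, c0, c0 + 2000, "+", role=role))

    gene_by_id = {g.gene_id: g for g in genes}

    # master-TF promoter peaks wherever the master is a planted regulator
    for a, b in adjacency:
        if a == seed_tf:
            g = gene_by_id[b]
            master_peaks.append(GenomicInterval(g.chrom, g.tss - 200, g.tss + 200))
    master_peaks = sorted(set(master_peaks), key=lambda iv: (iv.chrom, iv.start))

    # ----- genome sequence with planted consensus sites ----------------
    chrom_names = layout.chroms
    genome_arr = {
        c: rng_genome.integers(0, 4, size=cfg.chrom_length).astype(np.int8)
        for c in chrom_names
    }
    occurrences: list[dict] = []

    def plant(motif_tf: str, chrom: str, start: int) -> None:
        pwm = pwm_by_tf[motif_tf]
        codes = np.array([int(np.argmax(row)) for row in pwm.matrix], dtype=np.int8)
        genome_arr[chrom][start : start + pwm.width] = codes
        occurrences.append(
            {"motif": pwm.name, "tf": motif_tf, "chrom": chrom, "start": int(start), "strand": "+"}
        )

    # regulator sites in promoter DHSs (the circuit edges)
    for tf_target, prom in promoter_sites:
        regulators = sorted(a for a, b in adjacency if b == tf_target)
        off = prom.start + 10
        for a in regulators:
            if off + pwm_by_tf[a].width > prom.end:
                raise ValueError(
                    f"promoter DHS of {tf_target} too small for {len(regulators)} regulator sites"
                )
            plant(a, prom.chrom, off)
            off += pwm_by_tf[a].width + 4
    # master consensus in every master ChIP peak lacking one
    planted_spans = {
        (o["chrom"], o["start"], o["start"] + pwm_by_tf[o["tf"]].width) for o in occurrences
    }
    for mp in master_peaks:
        has = any(
            c == mp.chrom and s >= mp.start and e <= mp.end for c, s, e in planted_spans
        )
        if not has:
            plant(seed_tf, mp.chrom, mp.start + 50)

    _cleanup_dhs(cfg, genome_arr, [iv for iv, _ in dhs], pwms, occurrences, rng_clean)

    genome = {c: "".join(BASES[i] for i in genome_arr[c]) for c in chrom_names}

    # ----- H3K27ac signal ----------------------------------------------
    n_runs = cfg.chrom_length // _RUN
    runs: list[tuple[str, int, int, float]] = []
    for c in chrom_names:
        values = rng_bg.gamma(shape=4.0, scale=cfg.background_mean / 4.0, size=n_runs)
        add = np.zeros(n_runs)
        for iv, amp, _name in h3k_peaks:
            if iv.chrom != c:
                continue
            add[iv.start // _RUN : iv.end // _RUN] += (amp - 1.0) * cfg.background_mean
        values = values + add
        starts = np.arange(n_runs) * _RUN
        runs.extend((c, int(s), int(s + _RUN), float(v)) for s, v in zip(starts, values))
    track = SignalTrack.from_runs(runs)

    # ----- expression matrix -------------------------------------------
    expr_tissues = [FOCAL_TISSUE] + [f"tissue_{i:02d}" for i in range(1, cfg.n_expression_tissues)]
    specific_genes = idg_se + idg_enh + ["DEC_SE_NOTF"] + spec_plain
    tpm = np.zeros((len(genes), len(expr_tissues)))
    for i, g in enumerate(genes):
        if g.gene_id in specific_genes:
            row = rng_expr.uniform(0.5, 1.5, size=len(expr_tissues))
            row[0] = 500.0
        elif g.gene_id in ("DEC_SE_LOWEXPR", tf_low):
            row = rng_expr.uniform(5.0, 15.0, size=len(expr_tissues))
            row[0] = 10.0
        elif g.role == "tf":
            row = rng_expr.uniform(120.0, 180.0, size=len(expr_tissues))
            row[0] = 200.0
        else:
            mu = rng_expr.uniform(10.0, 80.0)
            row = mu * rng_expr.uniform(0.8, 1.2, size=len(expr_tissues))
        tpm[i] = row
    expr = pd.DataFrame(tpm, index=[g.gene_id for g in genes], columns=expr_tissues)

    # ----- SNP panels ---------------------------------------------------
    se_union = [rec["interval"] for rec in focal_se]
    se_lengths = np.array([len(iv) for iv in se_union])
    se_cum = np.cumsum(se_lengths)

    def random_alt(chrom: str, pos: int) -> tuple[str, str]:
        ref_code = int(genome_arr[chrom][pos])
        alt_code = (ref_code + 1 + int(rng_snp.integers(0, 3))) % 4
        return BASES[ref_code], BASES[alt_code]

    enriched: list[SnpRecord] = []
    enriched_truth: list[dict] = []
    for i in range(cfg.n_enriched_snps):
        in_se = bool(rng_snp.random() < cfg.snp_se_fraction)
        if in_se:
            u = int(rng_snp.integers(0, se_cum[-1]))
            k = int(np.searchsorted(se_cum, u, side="right"))
            iv = se_union[k]
            pos = iv.start + (u - (se_cum[k - 1] if k else 0))
            chrom = iv.chrom
        else:
            # rejection-sample a position outside every planted SE so the
            # manifest membership flag matches the emitted coordinates
            while True:
                chrom = chrom_names[int(rng_snp.integers(0, len(chrom_names)))]
                pos = int(rng_snp.integers(0, cfg.chrom_length))
                if not any(
                    iv.chrom == chrom and iv.start <= pos < iv.end for iv in se_union
                ):
                    break
        ref, alt = random_alt(chrom, pos)
        snp = SnpRecord(f"rs_e{i:04d}", chrom, pos, ref, alt, trait="PTH_level")
        enriched.append(snp)
        enriched_truth.append({"snp_id": snp.snp_id, "in_se": in_se})
    control: list[SnpRecord] = []
    for i in range(cfg.n_control_snps):
        chrom = chrom_names[int(rng_snp.integers(0, len(chrom_names)))]
        pos = int(rng_snp.integers(0, cfg.chrom_length))
        ref, alt = random_alt(chrom, pos)
        control.append(SnpRecord(f"rs_c{i:04d}", chrom, pos, ref, alt, trait="control"))

    # ----- allele counts at heterozygous sites inside master peaks ------
    allele_rows = []
    allele_truth: dict[str, float] = {}
    n_imbalanced = int(round(cfg.n_het_sites * cfg.imbalanced_site_fraction))
    for i in range(cfg.n_het_sites):
        mp = master_peaks[i % len(master_peaks)]
        pos = mp.start + (20 + 7 * i) % len(mp)
        frac = cfg.imbalance_fraction if i < n_imbalanced else 0.5
        depth = max(1, int(rng_allele.poisson(cfg.allele_depth_mean)))
        ref_n = int(rng_allele.binomial(depth, frac))
        ref, alt = random_alt(mp.chrom, pos)
        sid = f"rs_h{i:03d}"
        allele_rows.append(
            {
                "snp_id": sid,
                "chrom": mp.chrom,
                "pos": pos + 1,
                "ref": ref,
                "alt": alt,
                "ref_count": ref_n,
                "alt_count": depth - ref_n,
            }
        )
        allele_truth[sid] = frac
    allele_df = pd.DataFrame(allele_rows)

    # ----- loops: distal typical enhancers to plain-gene TSSs -----------
    loops: list[LoopRecord] = []
    loop_truth: list[dict] = []
    fillers = [g for g in genes if g.role == "filler"]
    loop_pairs: list[tuple[GenomicInterval, _Gene]] = []
    for iv in typical[5:]:
        candidates = [
            g for g in fillers
            if g.chrom == iv.chrom and abs(g.tss - iv.midpoint) >= 50_000
            and all(g is not p[1] for p in loop_pairs)
        ]
        if candidates:
            loop_pairs.append((iv, candidates[0]))
        if len(loop_pairs) == cfg.n_loops:
            break
    for iv, g in loop_pairs:
        a1 = GenomicInterval(iv.chrom, max(0, iv.midpoint - 2500), iv.midpoint + 2500)
        a2 = GenomicInterval(g.chrom, max(0, g.tss - 2500), g.tss + 2500)
        pair = sorted([a1, a2], key=lambda x: (x.chrom, x.start))
        loops.append(LoopRecord(pair[0], pair[1], score=0.01))
        loop_truth.append(
            {"enhancer": [iv.chrom, iv.start, iv.end], "gene": g.gene_id}
        )

    # ----- segmentations -------------------------------------------------
    segmentations = {
        t: _build_segmentation(cfg, t, chrom_names, genes, focal_se, other_se, typical, enh_elements)
        for t in cfg.tissues
    }

    # ----- write the bundle ----------------------------------------------
    outdir.mkdir(parents=True, exist_ok=True)
    rio.write_fasta(genome, outdir / "genome.fa")
    rio.write_chrom_sizes({c: cfg.chrom_length for c in chrom_names}, outdir / "chrom_sizes.tsv")
    gene_models = [
        GeneModel(g.gene_id, GenomicInterval(g.chrom, g.start, g.end, g.strand), g.strand)
        for g in genes
    ]
    rio.write_gene_models(gene_models, outdir / "genes.tsv")
    rio.write_bedgraph(track, outdir / "h3k27ac.bedgraph")
    rio.write_bed(
        [Peak(iv, name=name) for iv, _amp, name in h3k_peaks], outdir / "h3k27ac_peaks.bed"
    )
    rio.write_bed(
        [Peak(iv, name=f"tfpeak_{i}") for i, iv in enumerate(master_peaks)],
        outdir / "tf_peaks.bed",
    )
    rio.write_bed(
        [Peak(iv, name=f"dhs_{i}") for i, (iv, _k) in enumerate(dhs)], outdir / "dhs.bed"
    )
    for t, seg in segmentations.items():
        rio.write_state_bed(seg, outdir / f"states_{t}.bed")
    se_sets = {FOCAL_TISSUE: [rec["interval"] for rec in focal_se], **other_se}
    for t, ivs in se_sets.items():
        rio.write_bed(
            [Peak(iv, name=f"{t}_se_{i}") for i, iv in enumerate(ivs)],
            outdir / f"se_{t}.bed",
        )
    rio.write_tsv_matrix(expr, outdir / "expression_tpm.tsv", index_label="gene_id")
    rio.write_meme_pwm(pwms, outdir / "motifs.meme")
    with open(outdir / "motif_map.tsv", "w", encoding="utf-8") as fh:
        fh.write("motif\ttf\n")
        for tf in tf_names:
            fh.write(f"{pwm_by_tf[tf].name}\t{tf}\n")
    rio.write_snps(enriched, outdir / "snps_enriched.tsv")
    rio.write_snps(control, outdir / "snps_control.tsv")
    rio.write_allele_counts(allele_df, outdir / "allele_counts.tsv")
    rio.write_bedpe(loops, outdir / "loops.bedpe")

    manifest = TruthManifest(
        config=dataclasses.asdict(cfg),
        tissues=cfg.tissues,
        focal=FOCAL_TISSUE,
        se_intervals={
            t: [[iv.chrom, iv.start, iv.end] for iv in ivs] for t, ivs in se_sets.items()
        },
        specific_genes=sorted(specific_genes),
        identity_genes=sorted(idg_se + idg_enh),
        decoys={
            "DEC_SE_LOWEXPR": "specific SE + master binding, low expression",
            "DEC_SE_NOTF": "specific SE + specific expression, no master binding",
            "DEC_EXPR_NOEL": "specific expression, no specific element",
            tf_low: "circuit TF decoy: motif + SE, low expression",
            tf_nose: "circuit TF decoy: motif + expression, no SE",
        },
        circuit_tfs=core_tfs,
        seed_tf=seed_tf,
        apex_tf=apex_tf,
        circuit_edges=[[a, b] for a, b in adjacency],
        motif_occurrences=occurrences,
        enriched_snps=enriched_truth,
        allele_truth=allele_truth,
        loops=loop_truth,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _cleanup_dhs(
    cfg: SimulationConfig,
    genome_arr: dict[str, np.ndarray],
    dhs_ivs: list[GenomicInterval],
    pwms: list[PWM],
    occurrences: list[dict],
    rng: np.random.Generator,
) -> None:
    """Resample DHS background until only planted motif occurrences remain."""
    thresholds = {p.name: pwm_pvalue_threshold(p, cfg.motif_p_target) for p in pwms}
    max_w = max(p.width for p in pwms)
    planted = {}
    widths = {o["motif"]: next(p.width for p in pwms if p.name == o["motif"]) for o in occurrences}
    for o in occurrences:
        planted.setdefault(o["chrom"], []).append((o["start"], o["start"] + widths[o["motif"]], o["motif"]))
    protected = {
        c: sorted((s, e) for s, e, _m in spans) for c, spans in planted.items()
    }
    for iv in dhs_ivs:
        lo = max(0, iv.start - max_w + 1)
        hi = min(len(genome_arr[iv.chrom]), iv.end + max_w - 1)
        spans = planted.get(iv.chrom, [])
        for _attempt in range(200):
            seq = "".join(BASES[i] for i in genome_arr[iv.chrom][lo:hi])
            bad = False
            for pwm in pwms:
                for h in scan_sequence(seq, pwm, thresholds[pwm.name]):
                    h_start = lo + h.interval.start
                    h_end = lo + h.interval.end
                    if h_end <= iv.start or h_start >= iv.end:
                        continue  # outside the DHS proper
                    ok = any(
                        s < h_end and h_start < e and m == pwm.name for s, e, m in spans
                    )
                    if not ok:
                        bad = True
                        break
                if bad:
                    break
            if not bad:
                break
            # resample unprotected positions in [lo, hi)
            prot = protected.get(iv.chrom, [])
            mask = np.ones(hi - lo, dtype=bool)
            for s, e in prot:
                s2, e2 = max(s, lo), min(e, hi)
                if s2 < e2:
                    mask[s2 - lo : e2 - lo] = False
            fresh = rng.integers(0, 4, size=int(mask.sum())).astype(np.int8)
            genome_arr[iv.chrom][lo:hi][mask] = fresh
        else:
            raise RuntimeError(f"could not clean background hits from DHS {iv}")


def _build_segmentation(
    cfg: SimulationConfig,
    tissue: str,
    chrom_names: list[str],
    genes: list[_Gene],
    focal_se: list[dict],
    other_se: dict[str, list[GenomicInterval]],
    typical: list[GenomicInterval],
    enh_elements: list[tuple[GenomicInterval, str]],
) -> StateSegmentation:
    labeled: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chrom_names}
    for g in genes:
        labeled[g.chrom].append((max(0, g.tss - 400), g.tss + 400, "TssA"))
    focal_ivs = [rec["interval"] for rec in focal_se]
    if tissue == FOCAL_TISSUE:
        for iv in focal_ivs:
            labeled[iv.chrom].append((iv.start, iv.end, "EnhA1"))
        for iv in typical:
            labeled[iv.chrom].append((iv.start, iv.end, "EnhA2"))
        for iv, _g in enh_elements:
            labeled[iv.chrom].append((iv.start, iv.end, "EnhA2"))
        for t, ivs in other_se.items():
            for iv in ivs:
                if iv not in focal_ivs:
                    labeled[iv.chrom].append((iv.start, iv.end, "ReprPC"))
    else:
        own = other_se.get(tissue, [])
        own_set = set(own)
        for iv in own:
            labeled[iv.chrom].append((iv.start, iv.end, "EnhA1"))
        for iv in focal_ivs:
            if iv not in own_set:
                labeled[iv.chrom].append((iv.start, iv.end, "ReprPC"))
        for iv in typical:
            labeled[iv.chrom].append((iv.start, iv.end, "ReprPC"))
        for iv, _g in enh_elements:
            labeled[iv.chrom].append((iv.start, iv.end, "ReprPC"))
        for t, ivs in other_se.items():
            if t == tissue:
                continue
            for iv in ivs:
                if iv not in own_set and iv not in focal_ivs:
                    labeled[iv.chrom].append((iv.start, iv.end, "ReprPC"))
    segments = []
    for c in chrom_names:
        spans = sorted(set(labeled[c]))
        merged: list[tuple[int, int, str]] = []
        for s, e, st in spans:
            if merged and s < merged[-1][1]:
                raise ValueError(f"planted state segments overlap on {c}: {merged[-1]} vs {(s, e, st)}")
            merged.append((s, e, st))
        cursor = 0
        for s, e, st in merged:
            if s > cursor:
                segments.append((c, cursor, s, "Quies"))
            segments.append((c, s, e, st))
            cursor = e
        if cursor < cfg.chrom_length:
            segments.append((c, cursor, cfg.chrom_length, "Quies"))
    return StateSegmentation(tissue, segments)


def worked_example_allele_counts() -> pd.DataFrame:
    """The printed worked example of allelic imbalance as a one-row table.

    A heterozygous regulatory SNP covered by 88 ChIP-seq reads, 59
    supporting the reference allele and 29 the alternative (67% / 33%).
    Round-trips through the allele-count TSV reader.
    """
    return pd.DataFrame(
        [
            {
                "snp_id": "rs9811123",
                "chrom": "chr3",
                "pos": 122003769,
                "ref": "G",
                "alt": "A",
                "ref_count": 59,
                "alt_count": 29,
            }
        ]
    )
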