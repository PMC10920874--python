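"""Configuration, validation and the end-to-end pipeline driver.

``run_all`` drives super-enhancer calling, cross-tissue specificity,
chromatin-state annotation of the master-TF peaks, motif scanning over
open chromatin, circuit reconstruction, the identity-gene screen, GWAS
SNP enrichment and allelic imbalance, writing each stage's outputs under
a stage-named subdirectory plus a consolidated ``report.json``.  Reruns
on identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .annotation import (
    classify_peaks,
    filter_peaks_by_dhs,
    assign_peak_to_state,
    state_enrichment,
)
from .circuit import build_circuit, connectivity_ranking, top_of_hierarchy
from .intervals import GenomicInterval, Peak
from .motif import scan_genome
from .specificity import (
    assign_elements_to_genes,
    expression_zscores,
    identity_gene_screen,
    tissue_specific_elements,
)
from .stats import allelic_imbalance, permutation_enrichment, snp_feature_overlap
from .superenhancer import (
    call_super_enhancers,
    cross_tissue_se_specificity,
    rank_by_signal,
    stitch_enhancers,
)

_PATH_KEYS = [
    "h3k27ac_peaks",
    "h3k27ac_signal",
    "tf_peaks",
    "dhs",
    "genes",
    "expression",
    "motifs",
    "motif_map",
    "genome_fasta",
    "chrom_sizes",
    "snps",
    "background_snps",
    "allele_counts",
]
_OPTIONAL_PATH_KEYS = ["input_signal", "loops"]


@dataclass
class PipelineConfig:
    """All file paths and tunables of one end-to-end run."""

    paths: dict[str, str]
    state_beds: dict[str, str]  # tissue -> dense state BED
    se_beds: dict[str, str]  # tissue -> SE BED (non-focal tissues)
    focal_tissue: str
    seed_tf: str
    outdir: str
    stitch_distance: int = 12500
    tss_exclusion: bool = False
    proximal_window: int = 2000
    z_min: float = 7.0
    tpm_min: float = 50.0
    motif_p: float = 1e-4
    circuit_window: int = 5000
    min_overlap_fraction: float = 0.25
    n_perm: int = 999
    seed: int = 7


def validate_config(raw: dict) -> PipelineConfig:
    """Normalize a raw config mapping, reporting every error at once."""
    errors: list[str] = []
    paths = dict(raw.get("paths") or {})
    for key in _PATH_KEYS:
        if key not in paths:
            errors.append(f"missing required path: {key}")
        elif not Path(paths[key]).exists():
            errors.append(f"path for {key!r} does not exist: {paths[key]}")
    for key in _OPTIONAL_PATH_KEYS:
        if key in paths and not Path(paths[key]).exists():
            errors.append(f"path for {key!r} does not exist: {paths[key]}")
    for key, present in (("state_beds", True), ("se_beds", True)):
        for tissue, p in (raw.get(key) or {}).items():
            if not Path(p).exists():
                errors.append(f"{key}[{tissue}] does not exist: {p}")
    if not raw.get("focal_tissue"):
        errors.append("focal_tissue is required")
    if not raw.get("seed_tf"):
        errors.append("seed_tf is required")
    if not raw.get("outdir"):
        errors.append("outdir is required")
    numeric_bounds = {
        "stitch_distance": (0, 10**7),
        "proximal_window": (1, 10**6),
        "z_min": (0, 100),
        "tpm_min": (0, 10**6),
        "motif_p": (1e-12, 1.0),
        "circuit_window": (1, 10**6),
        "min_overlap_fraction": (0.0, 1.0),
        "n_perm": (1, 10**6),
    }
    cfg_kwargs = {}
    for name, (lo, hi) in numeric_bounds.items():
        if name in raw:
            val = raw[name]
            if not (lo <= val <= hi):
                errors.append(f"{name}={val} outside [{lo}, {hi}]")
            else:
                cfg_kwargs[name] = val
    if errors:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))
    return PipelineConfig(
        paths=paths,
        state_beds=dict(raw.get("state_beds") or {}),
        se_beds=dict(raw.get("se_beds") or {}),
        focal_tissue=raw["focal_tissue"],
        seed_tf=raw["seed_tf"],
        outdir=raw["outdir"],
        tss_exclusion=bool(raw.get("tss_exclusion", False)),
        seed=int(raw.get("seed", 7)),
        **cfg_kwargs,
    )


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


def config_for_bundle(bundle_dir, outdir, seed: int = 7, n_perm: int = 999) -> PipelineConfig:
    """A PipelineConfig wired to the files a synthetic bundle emits."""
    from .simulate import FOCAL_TISSUE, TruthManifest

    b = Path(bundle_dir)
    manifest = TruthManifest.load(b / "manifest.json")
    paths = {
        "h3k27ac_peaks": str(b / "h3k27ac_peaks.bed"),
        "h3k27ac_signal": str(b / "h3k27ac.bedgraph"),
        "tf_peaks": str(b / "tf_peaks.bed"),
        "dhs": str(b / "dhs.bed"),
        "genes": str(b / "genes.tsv"),
        "expression": str(b / "expression_tpm.tsv"),
        "motifs": str(b / "motifs.meme"),
        "motif_map": str(b / "motif_map.tsv"),
        "genome_fasta": str(b / "genome.fa"),
        "chrom_sizes": str(b / "chrom_sizes.tsv"),
        "snps": str(b / "snps_enriched.tsv"),
        "background_snps": str(b / "snps_control.tsv"),
        "allele_counts": str(b / "allele_counts.tsv"),
        "loops": str(b / "loops.bedpe"),
    }
    return PipelineConfig(
        paths=paths,
        state_beds={t: str(b / f"states_{t}.bed") for t in manifest.tissues},
        se_beds={t: str(b / f"se_{t}.bed") for t in manifest.tissues if t != FOCAL_TISSUE},
        focal_tissue=FOCAL_TISSUE,
        seed_tf=manifest.seed_tf,
        outdir=str(outdir),
        seed=seed,
        n_perm=n_perm,
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the consolidated report dictionary."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": dataclasses.asdict(cfg)}

    def stage(name):
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    try:
        name = "call_se"
        d = stage(name)
        peaks = rio.read_bed(cfg.paths["h3k27ac_peaks"])
        track = rio.read_bedgraph(cfg.paths["h3k27ac_signal"])
        genes = rio.read_gene_models(cfg.paths["genes"])
        input_track = (
            rio.read_bedgraph(cfg.paths["input_signal"])
            if "input_signal" in cfg.paths
            else None
        )
        stitched = stitch_enhancers(
            peaks,
            stitch_distance=cfg.stitch_distance,
            tss_exclusion=genes if cfg.tss_exclusion else None,
        )
        ranked = rank_by_signal(stitched, track, input_track)
        call = call_super_enhancers(ranked)
        with open(d / "all_enhancers.bed", "w", encoding="utf-8") as fh:
            for e, is_se in zip(call.enhancers, call.is_super):
                iv = e.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\trank_{e.rank}\t{e.signal:.4f}"
                    f"\t.\t{int(is_se)}\n"
                )
        se_intervals = [e.interval for e in call.super_enhancers]
        rio.write_bed(
            [Peak(iv, name=f"SE_{i + 1}") for i, iv in enumerate(se_intervals)],
            d / "super_enhancers.bed",
        )
        report["n_stitched"] = len(call.enhancers)
        report["n_super_enhancers"] = call.cutoff_index

        name = "se_specificity"
        d = stage(name)
        se_sets = {cfg.focal_tissue: se_intervals}
        for tissue, path in cfg.se_beds.items():
            se_sets[tissue] = [p.interval for p in rio.read_bed(path)]
        specific = cross_tissue_se_specificity(
            se_sets, cfg.focal_tissue, cfg.min_overlap_fraction
        )
        with open(d / "se_specific.tsv", "w", encoding="utf-8") as fh:
            fh.write("chrom\tstart\tend\tspecific\n")
            for iv in se_intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{int(specific[iv])}\n")
        report["n_specific_se"] = int(sum(specific.values()))

        name = "annotate_states"
        d = stage(name)
        tf_peaks = rio.read_bed(cfg.paths["tf_peaks"])
        dhs_peaks = rio.read_bed(cfg.paths["dhs"])
        dhs = [p.interval for p in dhs_peaks]
        tf_kept = filter_peaks_by_dhs(tf_peaks, dhs)
        seg = rio.read_state_bed(cfg.state_beds[cfg.focal_tissue], cfg.focal_tissue)
        assignments = [assign_peak_to_state(p, seg) for p in tf_kept]
        enr = state_enrichment(assignments, seg)
        position = classify_peaks(tf_kept, genes, cfg.proximal_window)
        with open(d / "tf_peak_states.tsv", "w", encoding="utf-8") as fh:
            fh.write("peak\tstate\tposition\n")
            for p, st, pos in zip(tf_kept, assignments, position):
                fh.write(f"{p.name}\t{st}\t{pos}\n")
        with open(d / "state_enrichment.tsv", "w", encoding="utf-8") as fh:
            fh.write("state\tobserved\texpected\tratio\tpvalue\n")
            for st in enr.observed:
                fh.write(
                    f"{st}\t{enr.observed[st]}\t{enr.expected.get(st, 0):.3f}"
                    f"\t{enr.ratio.get(st, float('nan')):.4f}\t{enr.pvalue.get(st, 1):.3g}\n"
                )
        active = {"TssA", "TssFlnk", "TssFlnkU", "TssFlnkD", "EnhA1", "EnhA2"}
        report["n_tf_peaks_dhs"] = len(tf_kept)
        report["tf_peak_active_fraction"] = (
            float(np.mean([a in active for a in assignments])) if assignments else 0.0
        )

        name = "scan_motifs"
        d = stage(name)
        genome = rio.read_fasta(cfg.paths["genome_fasta"])
        pwms = rio.read_meme_pwm(cfg.paths["motifs"])
        motif_map_df = pd.read_csv(cfg.paths["motif_map"], sep="\t")
        motif_to_tf = dict(zip(motif_map_df["motif"], motif_map_df["tf"]))
        expr = rio.read_tsv_matrix(cfg.paths["expression"])
        expressed = {
            tf
            for tf in motif_to_tf.values()
            if tf in expr.index and expr.loc[tf, cfg.focal_tissue] > cfg.tpm_min
        }
        scan_pwms = [p for p in pwms if motif_to_tf.get(p.name) in expressed]
        hits = scan_genome(genome, scan_pwms, p_target=cfg.motif_p, regions=dhs)
        with open(d / "motif_hits.tsv", "w", encoding="utf-8") as fh:
            fh.write("motif\tchrom\tstart\tend\tstrand\tscore\tpvalue\n")
            for h in hits:
                fh.write(
                    f"{h.motif_id}\t{h.interval.chrom}\t{h.interval.start}"
                    f"\t{h.interval.end}\t{h.strand}\t{h.score:.3f}\t{h.pvalue:.3g}\n"
                )
        report["n_motif_hits"] = len(hits)

        name = "build_circuit"
        d = stage(name)
        se_links = assign_elements_to_genes(se_intervals, genes)
        se_genes = {l.gene_id for l in se_links}
        expr_tpm = {g.gene_id: float(expr.loc[g.gene_id, cfg.focal_tissue]) for g in genes if g.gene_id in expr.index}
        candidates = sorted(set(motif_to_tf.values()))
        graph = build_circuit(
            seed_tf=cfg.seed_tf,
            candidate_tfs=candidates,
            expr_tpm=expr_tpm,
            se_membership={tf: tf in se_genes for tf in candidates},
            dhs=dhs,
            motif_hits=hits,
            motif_to_tf=motif_to_tf,
            gene_models=genes,
            tpm_min=cfg.tpm_min,
            window=cfg.circuit_window,
        )
        (d / "edges.tsv").write_text(graph.to_edge_table())
        (d / "nodes.tsv").write_text(graph.to_node_table())
        report["circuit_nodes"] = sorted(graph.nodes)
        report["circuit_edges"] = [list(e) for e in graph.edges]
        report["circuit_connectivity"] = connectivity_ranking(graph)
        report["circuit_apex"] = sorted(top_of_hierarchy(graph))

        name = "identity_genes"
        d = stage(name)
        spec_results = expression_zscores(
            expr, cfg.focal_tissue, z_min=cfg.z_min, tpm_min=cfg.tpm_min
        )
        # specific elements: called SEs plus focal enhancer peaks outside SEs,
        # compared against the other tissues' SE element sets
        enh_elements = [
            p.interval
            for p in peaks
            if not any(p.interval.overlaps(se) for se in se_intervals)
        ]
        element_sets = {cfg.focal_tissue: se_intervals + enh_elements}
        for tissue, ivs in se_sets.items():
            if tissue != cfg.focal_tissue:
                element_sets[tissue] = ivs
        el_specific = tissue_specific_elements(
            element_sets, cfg.focal_tissue, cfg.min_overlap_fraction
        )
        specific_elements = [iv for iv, flag in el_specific.items() if flag]
        loops = rio.read_bedpe(cfg.paths["loops"]) if "loops" in cfg.paths else None
        links = assign_elements_to_genes(specific_elements, genes, loops=loops)
        records = identity_gene_screen(spec_results, links, tf_kept, genes)
        with open(d / "identity_genes.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_id\tz\thas_specific_element\texpression_specific\ttf_target\tpasses\n")
            for r in records:
                fh.write(
                    f"{r.gene_id}\t{r.z:.3f}\t{int(r.has_specific_element)}"
                    f"\t{int(r.is_expression_specific)}\t{int(r.is_tf_target)}\t{int(r.passes)}\n"
                )
        passing = sorted(r.gene_id for r in records if r.passes)
        report["identity_genes"] = passing
        report["n_identity_genes"] = len(passing)

        name = "gwas_enrich"
        d = stage(name)
        snps = rio.read_snps(cfg.paths["snps"])
        bg_snps = rio.read_snps(cfg.paths["background_snps"])
        feature_sets = {
            "super_enhancer": se_intervals,
            "enhancer": enh_elements,
            "dhs": dhs,
        }
        fisher = snp_feature_overlap(snps, bg_snps, feature_sets)
        sizes = rio.read_chrom_sizes(cfg.paths["chrom_sizes"])
        perm = permutation_enrichment(
            snps, se_intervals, sizes, n_perm=cfg.n_perm, seed=cfg.seed
        )
        with open(d / "snp_enrichment.tsv", "w", encoding="utf-8") as fh:
            fh.write("feature\tin_trait\tin_background\todds_ratio\tpvalue\n")
            for fname, res in fisher.items():
                fh.write(
                    f"{fname}\t{res.table[0][0]}\t{res.table[1][0]}"
                    f"\t{res.odds_ratio:.4f}\t{res.pvalue:.3g}\n"
                )
        report["snp_fisher"] = {
            k: {"odds_ratio": v.odds_ratio, "pvalue": v.pvalue} for k, v in fisher.items()
        }
        report["snp_permutation"] = {
            "observed": perm.observed,
            "n_perm": perm.n_perm,
            "pvalue": perm.pvalue,
        }

        name = "allelic_imbalance"
        d = stage(name)
        counts = rio.read_allele_counts(cfg.paths["allele_counts"])
        rows = []
        for row in counts.itertuples(index=False):
            res = allelic_imbalance(row.ref_count, row.alt_count)
            rows.append(
                {
                    "snp_id": row.snp_id,
                    "depth": res.depth,
                    "ref_fraction": res.ref_fraction,
                    "pvalue": res.pvalue,
                }
            )
        pd.DataFrame(rows).to_csv(d / "allelic_imbalance.tsv", sep="\t", index=False)
        report["n_imbalanced_sites"] = int(sum(1 for r in rows if r["pvalue"] < 0.05))
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise StageError(name, exc) from exc

    report["input_hashes"] = {
        key: _sha256(path) for key, path in sorted(cfg.paths.items())
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
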