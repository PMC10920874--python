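# regland

A Python toolkit for dissecting the regulatory landscape of a tissue from
chromatin data: super-enhancer calling, cross-tissue specificity, core
regulatory circuit reconstruction around a master transcription factor,
chromatin-state annotation of TF binding, GWAS-SNP enrichment, and
allele-specific binding imbalance.  It is aimed at regulatory-genomics
analysts who have peak calls, signal tracks, chromatin-state segmentations,
open-chromatin sites, expression matrices and motif libraries for a focal
tissue (the motivating case is a small endocrine tissue such as the
parathyroid, profiled against a large multi-tissue reference panel) and want
a tested, deterministic reimplementation of the standard integrative
analyses.

Because the real datasets of such studies are typically controlled-access,
the package ships a first-class synthetic-data generator that emits every
input format with planted ground truth (a JSON manifest), so the entire
pipeline is testable end-to-end on any machine.

## Methods at a glance

- **Super-enhancers** (`regland.superenhancer`). H3K27ac peaks whose gaps are
  below 12.5 kb are stitched; stitched regions are ranked by input-subtracted
  signal area `s_i = max(0, ∫ChIP − ∫input)`; with both axes of the ascending
  rank–signal curve scaled to [0, 1], the cutoff is the tangent point of a
  slope-1 line (the index minimizing `y − x`), and regions strictly above the
  cutoff signal are super-enhancers. A focal SE is *tissue-specific* when it
  appears (≥ 25% overlap of its length) in no more than one other tissue.
- **Motifs** (`regland.motif`). Windows are scored by `Σ log2(p_i(b)/q(b))`;
  the score threshold at a target p-value (default 1e-4) comes from the exact
  null score distribution computed by convolution on a 1e-3-bit grid, so
  per-hit p-values are exact, not empirical. Control sequences for motif
  enrichment are dinucleotide-preserving shuffles.
- **Circuit** (`regland.circuit`). A directed edge A → B means a motif hit of
  A inside a DNase hypersensitive site within ±5 kb of B's TSS; nodes must be
  expressed (TPM > 50) and super-enhancer associated; autoregulation is a
  self-edge and connectivity is in-degree + out-degree.
- **Specificity and identity genes** (`regland.specificity`). A gene is
  expression-specific when `z = (TPM_focal − mean)/SD > 7` across tissues
  (sample SD, focal included) and focal TPM > 50; identity genes additionally
  need a linked tissue-specific enhancer/SE and a master-TF peak on the gene
  body or linked element.
- **Enrichment statistics** (`regland.stats`). One-sided Fisher's exact tests
  (hypergeometric tail), a permutation null drawing length-matched
  non-overlapping random regions with add-one empirical p, and the exact
  two-sided binomial test of allele read counts against 0.5.

## Worked example

```python
from regland.stats import allelic_imbalance
res = allelic_imbalance(59, 29)   # ref/alt ChIP reads at a het SNP
print(res.depth, round(100 * res.ref_fraction), round(res.pvalue, 4))
# 88 67 0.0018
```

Of 88 reads covering the heterozygous site, 67% support the reference
allele — a significant imbalance (exact binomial p ≈ 0.002), evidence that
the variant alters local regulatory activity.

End-to-end on synthetic data (`python examples/01_call_super_enhancers.py`):

```
stitched regions : 39
super-enhancers  : 16 (planted: 16)
strongest region : chr1:320200-332200 signal=106573
weakest region   : signal=960
```

The slope-1 tangent cutoff separates the 16 planted super-enhancers
(~100-fold the signal area of typical enhancers) exactly. See `examples/`
for circuit reconstruction, motif scanning, GWAS enrichment and the
identity-gene screen, each printing the numbers it computes.

A thin CLI mirrors the library: `regland simulate | call-se |
se-specificity | annotate-states | scan-motifs | gwas-enrich |
allelic-imbalance | run-all`.

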