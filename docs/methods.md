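# Methods

This note documents the models, statistical conventions and design
choices behind `regland`, in the spirit of the methods documentation of
packages like statsmodels or msprime: what each procedure assumes, which
knobs matter, and what the synthetic-data suite does and does not
establish about real data.

## Coordinates and interval logic

All internal coordinates are 0-based half-open (BED convention); SNP
tables are 1-based on disk and converted on read. Overlap is defined as
≥ 1 bp of shared span and is strand-blind everywhere; strand enters only
TSS derivation (start for `+`, end − 1 for `−`) and motif scanning.
Chromosomes present in only one of two interval sets yield zero
overlaps, not errors, so synthetic and real contig sets can be mixed.
Signal tracks are sparse step functions; `signal_sum` is the exact area
(value × bp) over the query and is additive over partitions.

## Super-enhancer calling

The caller follows the conventional stitch–rank–cutoff procedure:

1. **Stitching.** Peaks chained by gaps strictly below the stitch
   distance (default 12,500 bp) merge into one region. Optional promoter
   exclusion removes peaks lying fully within ±2,500 bp of a TSS before
   stitching; it is off by default and exposed as a flag, since its use
   is dataset-dependent.
2. **Ranking.** Region signal is `max(0, area(ChIP) − area(input))`;
   ties are broken by genomic order so ranking is deterministic.
3. **Cutoff.** With signals sorted ascending and both axes rescaled to
   [0, 1], the ranked-signal curve of a tissue is a convex "hockey
   stick"; the super-enhancer boundary is the tangent point of a slope-1
   line on this curve. For a convex ascending curve that tangent point
   is the index minimizing `y − x`, and regions whose signal is strictly
   above the cutoff signal are called super-enhancers. A flat curve has
   no tangent point and yields an empty SE set; at least two regions are
   required. The discrete argmin form is exact and oracle-checkable
   (tests compare it against a direct per-index scan on random curves),
   with no smoothing parameters.

Cross-tissue comparison: a focal SE is "shared with" tissue *t* when any
SE of *t* covers at least a fraction (default 0.25) of the focal SE's
length, and is *specific* when shared with at most one other tissue.
The overlap fraction is a declared convention — coordinate-identity
would be too strict across independently processed tissues, and any-bp
overlap too lax — and is exposed in configuration.

## Chromatin-state annotation

Peaks are assigned to the state with maximal bp overlap; exact ties go
to the earlier state in the 18-state vocabulary (Roadmap expanded-model
mnemonics, TssA first), making assignment deterministic. State
enrichment compares the observed per-state peak counts with
`expected = N · state_bp / genome_bp` and reports observed/expected
ratios plus a one-sided Fisher p from the 2×2 table
`((obs_in, obs_out), (round(expected), N − round(expected)))` — i.e. the
peak set against a genome-composition draw of equal size. The background
margin is genome bp composition; this 2×2 construction is a declared
convention and is tested against hypergeometric enumeration.
TSS-proximal/distal classification uses the peak summit (midpoint when
no summit is recorded) and a strict `< 2,000 bp` distance to the nearest
TSS. Broad binding over a region is tested with the upper Poisson tail
`P(X ≥ k)`, λ = background rate × region length.

## Motif scanning and enrichment

PWM probabilities get a pseudocount (default 1e-3, renormalized) before
the log2-odds transform against the background composition. The null
score distribution under i.i.d. background is computed exactly by
convolving per-position score distributions on a discretized grid
(1e-3 bits; widths ≤ 25). The threshold for a target p (default 1e-4,
the conventional raw cutoff) is the smallest grid score whose upper tail
is ≤ the target; scanning quantizes window scores to the same grid, so
the admitted hit set matches full enumeration exactly (verified for
widths ≤ 8). Note two thresholds can differ numerically yet admit
identical hit sets when no attainable score lies between them; tests
therefore compare tail probabilities and admitted sets, not raw
thresholds. Both strands are scanned with one threshold; overlapping
hits are kept (no merging), and no multiple-testing correction is
applied to hits, matching the raw-p convention of motif-prevalence
analyses.

Motif enrichment in a region set uses one dinucleotide-preserving
shuffle per region (Altschul–Erikson Euler-path construction, seeded) as
its control and a one-sided Fisher test on regions-with-hit versus
controls-with-hit. Callers pre-filter the PWM battery to expressed TFs
(TPM > 50). The ref-vs-alt score delta at a SNP is exposed as a
descriptive statistic only; it is a single-method prediction, not a
consensus call.

## Core regulatory circuit

Candidate TFs enter the graph only if expressed above the TPM threshold
and associated with a super-enhancer (via element→gene links). The
expression cutoff for circuit membership is not separately standardized
anywhere we know of; the default mirrors the TPM > 50 filter used for
motif analyses and is flagged as an assumption. An edge A → B requires a
hit of A's motif inside a DHS that overlaps ±5 kb of B's TSS — hits in
naked sequence, or in DHSs outside the window, never create edges, and
gene-body hits beyond the window do not count. Multiple motifs mapping
to one TF are OR-combined. Autoregulation is a hit of a TF's own motif
in its own TSS window; connectivity is in-degree + out-degree; the "top
of hierarchy" query returns TFs with out-degree > 0 regulated by at most
k (default 1) distinct non-self TFs. Node and edge orderings are fully
deterministic, so serialized graphs are byte-stable.

## Specificity and the identity-gene screen

Expression specificity standardizes the focal tissue's TPM against the
across-tissue mean and sample SD (ddof = 1) with the focal tissue
included; zero-SD genes get z = 0 and are never specific. With the focal
tissue included, z is bounded by `(n−1)/√n`, so the z > 7 rule is only
attainable with a panel of roughly 50+ tissues — matching the scale of
public multi-tissue expression references. Elements link to genes by
nearest TSS (element midpoint) within 500 kb by default; chromatin loops
add links when one anchor overlaps the element and the other overlaps
±5 kb of a TSS, and each link carries its evidence label so either
channel can be audited. The identity screen is the conjunction of three
criteria — linked tissue-specific enhancer/SE, expression specificity,
and master-TF binding on the gene body or a linked element — and is
monotone: loosening any single threshold can only grow the passing set.

## Enrichment statistics

Fisher tests are one-sided hypergeometric tails; odds ratios use the
Haldane–Anscombe +0.5 correction only when a cell is zero, and the
result is flagged when so. The permutation null for "features in target
regions" draws, per replicate, |targets| non-overlapping regions
length-matched 1:1 to the targets, with chromosomes weighted by length
and placement uniform (rejection sampling, seeded; an error after 1,000
rejection rounds signals an over-full genome). Features are counted by
position (SNPs) or midpoint (intervals). The empirical p uses the
add-one correction `(1 + #{perm ≥ obs})/(1 + n_perm)`, so it is never
zero and its floor is 1/(1+n_perm) — consistent with reporting
resolution-limited values like "p < 0.001" at 999 permutations. Allelic
imbalance is the exact two-sided binomial test against 0.5 (summing all
outcomes no more probable than the observed), invariant to swapping
ref/alt. Benjamini–Hochberg correction is available but off by default;
raw p-values are the primary output.

## The synthetic-data generator

`regland.simulate` emits a complete input bundle — genome FASTA, gene
models, per-tissue 18-state segmentations, focal H3K27ac bedGraph and
peak BED, master-TF peak BED, DHS BED, per-tissue SE BEDs, a genes ×
tissues TPM matrix, MEME motif file with motif→TF map, enriched and
control SNP panels, allele-count table, loop BEDPE — plus a JSON truth
manifest. Design points:

- **What it emulates.** A 2 × 1 Mb genome carrying ~16 focal
  super-enhancers (10× background H3K27ac over 12 kb) and ~23 typical
  enhancers (2×) over piecewise-constant gamma background noise (200 bp
  runs; only relative amplitude matters to the caller); an 8-TF planted
  circuit with autoregulation and a designated apex TF, plus two decoy
  TFs that fail exactly one node filter each; 12 expression-specific
  genes of which 8 are identity genes (5 SE-linked, 3 enhancer-linked)
  and decoys failing exactly one screen criterion each; an enriched SNP
  panel with 80% of SNPs inside SEs versus a uniform control panel; and
  binomially imbalanced allele counts (default 0.67 ref fraction at half
  the sites, depth ~88).
- **Expression panel size.** 55 expression tissues (focal + 54): with the
  focal tissue included in the z-score the bound `(n−1)/√n` makes z > 7
  unattainable below ~51 tissues, so the generator validates this before
  writing anything. The chromatin panel (segmentations, SE sets) is 6
  tissues and independent of the expression panel.
- **Layout.** Features are placed as grid-aligned cassettes with ≥ 13 kb
  clearance between signal-bearing elements so stitching cannot bridge
  unrelated plants, and element→gene geometry guarantees each planted
  element's nearest TSS is its intended target. Requests that do not fit
  the genome raise before any file is written.
- **Exact planted truth.** After planting consensus motif occurrences
  (circuit edges in promoter DHSs, master-TF consensus in every master
  peak), the background sequence of every DHS is rejection-resampled
  until the emitted PWM battery at p ≤ 1e-4 has no unplanted hits there,
  with planted bases preserved. Recovered circuit edges therefore equal
  the planted adjacency by construction, which is what makes exact
  precision/recall a meaningful test of the analysis code rather than a
  statistical accident.
- **Determinism.** One seed sequence spawns fixed per-component RNG
  streams, so a given config + seed reproduces the bundle byte-for-byte
  and adding a component does not perturb the others.
- **What it does not model.** Read-level noise (no FASTQ/BAM), mappability
  and GC structure, cellular heterogeneity within a tissue, LD among
  SNPs, Hi-C contact matrices (loops are emitted directly), and
  correlated expression programs. Passing the recovery suites shows the
  pipeline's logic is correct under its stated assumptions, not that the
  thresholds are optimal for any particular real dataset.

## Problem sizes and numerical conventions

The test and acceptance suites run the full pipeline on 2 Mb genomes
(seconds per bundle), 10-seed SE-recovery batteries, 1,000-replicate
null calibrations of the permutation test (n_perm = 99 per run, 2,000
features, five 5 kb targets on 1 Mb — sizes chosen so the discrete count
statistic has few ties and the nominal level is meaningful), and a 1 Mb
background scan for motif-threshold calibration. Score quantization is
1e-3 bits; permutation p-values use add-one correction; all tie-breaks
(ranking, state assignment, graph serialization) are deterministic by
genomic or lexicographic order. Degenerate inputs have defined behavior
throughout: empty signal queries return 0, flat ranked-signal curves
return empty SE sets, zero-SD genes are non-specific, zero-depth allele
counts and empty region sets raise.

## Known limitations

- The slope-1 tangent on the discrete curve can shift by one rank when
  signals near the cutoff are nearly tied; the SE/typical boundary for
  such regions is inherently unstable in any implementation of this
  procedure.
- The Fisher background for state enrichment (genome-bp composition at
  equal draw size) and for SNP enrichment (an explicit background SNP
  panel) are declared conventions; other reasonable constructions give
  slightly different p-values.
- Motif-based circuit edges are predictions of binding opportunity, not
  occupancy; with real PWMs and real open chromatin the exact-recovery
  guarantees of the synthetic suite do not transfer.
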