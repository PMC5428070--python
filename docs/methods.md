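# Methods

This note documents the models, conventions, and numerical choices behind
`dietreg`, and what the synthetic-data tests do and do not demonstrate.

## Region annotation

Coordinates are 0-based half-open everywhere; conversion happens only at the
GTF boundary (GTF is 1-based inclusive). All window boundaries are
inclusive.

Categories and rules, for a region R and gene G with TSS t:

| category | rule |
|---|---|
| proximal_promoter | some base of R within 200 bp of t (two-sided) |
| distal_promoter | R overlaps the 5 kb window upstream of t |
| downstream | R overlaps the 5 kb window past the gene end |
| utr5 / utr3 / coding_exon / intron | R shares ≥ 1 base with the feature |
| distal_intergenic | no rule fires for any gene |

When several rules fire, precedence is proximal_promoter > utr5 > utr3 >
coding_exon > intron > distal_promoter > downstream: identity of transcribed
features outranks flanking windows, and the promoter window outranks
everything because a region touching the TSS is promoter-like regardless of
the annotation it overlaps. "Within 200 bp of the TSS" is read two-sided so
that the two promoter classes are disjoint (distal promoter is effectively
the remaining 0.2–5 kb upstream). Both choices are conventions; the rules as
published do not fix them. Among genes yielding the same category, the gene
with the nearest TSS (unsigned midpoint distance) is reported, with input
order as the final tie-break. Region-to-gene association for pooling regions
near gene sets uses the region midpoint within ±10 kb of the TSS, boundary
inclusive — an interval needs a single representative point there, while
category rules use the region's full extent.

## Motif model and scanning

A PSSM stores raw per-position probabilities (for information content,
computed in bits against its background with 0·log 0 = 0) and a
pseudocounted copy (p + 1e-3, renormalized) used for log-ratio scoring so
that LLR_min is finite. Motifs with total information content ≤ 8 bits are
dropped before scanning. Scores use natural logs; LLR_norm is invariant to
the log base.

Both strands are scanned (the reverse-complemented matrix over the same
window) and the best offset/strand kept; ambiguous bases contribute the
background probability, i.e. log-ratio 0. Match thresholds are calibrated
per motif as the (1 − fp) quantile of the best two-strand score on random
genomic k-mers of motif length (defaults: fp = 0.001, 5,000 samples; a
warning fires when samples < 1/fp). This is an empirical stand-in for a
database-supplied minimum-false-positive similarity cutoff; it is calibrated
on the analysis genome as given, so planted or real binding sites inflate
the null slightly and make the threshold conservative.

Match counting is binary per window (a window either contains ≥ 1 match or
none): the enrichment test is a window-level hypergeometric, which requires
exchangeable window-level units, not occurrence counts.

## CpG stratification

normalized CpG = observed CG dinucleotides / [(GC/2)² · (L−1)]. The (L−1)
factor counts overlapping dinucleotide positions and makes the ratio
scale-free; windows with GC = 0 are defined as 0 (maximally CpG-poor).
Windows exactly at the 0.5 threshold go to the low set, so the split is a
partition.

## Background sampling and the enrichment test

For each foreground window, one random genome window of equal length is
accepted when its GC fraction falls in the same 0.05-wide bin (rejection
sampling, 10,000 tries, then an error naming the bin). With k matching
foreground windows out of n, and K total matching windows out of N = |fg| +
|bg|, the enrichment p is the hypergeometric upper tail P(X ≥ k); BH
correction runs across the motif library, and again across the collapsed
family after clustering.

## Motif clustering

Dissimilarity between motifs a, b is the per-column mean of the symmetrized
KL divergence ½[KL(a‖b) + KL(b‖a)] (natural log, pseudocounted columns),
minimized over every ungapped offset with ≥ 1 overlapping column and over
the reverse complement of b; overhanging columns are compared to the
background. Similarity is the negated divergence, so the affinity-propagation
preference (−0.4 by default) lives on the divergence scale.

Affinity propagation is implemented directly (damping 0.9, max 1,000
iterations, convergence declared after 50 iterations with an unchanged
exemplar set) so tie-breaking is deterministic: a tiny index-ordered
perturbation replaces the random noise most implementations inject, and
argmax ties resolve to the lowest index. Exact duplicate motifs create a
known degeneracy — each copy waits for another to self-elect and none does —
which message passing alone does not resolve (reference implementations
stall the same way and fall back to a medoid refinement). After convergence,
any motif whose assigned exemplar is less similar than its own preference is
promoted to exemplar, lowest index first, until stable; this restores the
partition a posteriori without randomness. Per-cluster collapsing keeps the
minimum raw p (ties: larger foreground match count, then lexicographic motif
id) and is idempotent.

## Expression statistics

The differential filter is |log2FC| ≥ 0.5, q ≤ 0.05, and ≥ 0.1 FPKM in at
least one contrasted condition, all boundaries inclusive. The overlap test
needs an explicit gene-universe size — it is never inferred from the table,
because the choice dominates the p-value. Direction concordance uses
Fisher's exact test on [[up_up, up_down], [down_up, down_down]]; the default
report is the two-sided minimum-likelihood p (scipy's convention, verified
against complete enumeration), with the upper-tail p also available via the
hypergeometric tail. For the direction table (255, 183, 186, 71) the
two-sided p is 2.10e-14 and the upper tail 1.30e-14 — printed significance
bounds at this magnitude can differ by which convention a study used.

## ChIP tracks

Summit pairing is inclusive at ±100 bp and greedily one-to-one by smallest
distance (coordinate ties broken deterministically), which makes the pair
set symmetric in argument order. Pileups cap exact (position, strand)
duplicates at 2, extend + reads to [p, p+200) and − reads to (p−200, p],
scale by 1e6/library size (reads-per-million; library size defaults to the
retained read count), and smooth with a 120 bp moving average. The even
smoothing window is centered with the numpy `same`-convolution convention
(span [i−60, i+59]) and edges average over the truncated in-window span, so
constants are preserved and interior-supported mass is conserved.

## Synthetic data

The generator emulates the shape of the real inputs, not their biology:
i.i.d. genome bases at a target GC, widely spaced multi-exon genes (so that
5 kb flanks and ±10 kb TSS windows of neighbouring genes never collide —
13 kb margins per gene slot), peaks placed so their constructed category is
verified against the classifier at build time, consensus motif instances
planted into exactly round(rate · n) windows, reads scattered normally
(σ = 100 bp, truncated at ±300 bp) around summits, and an expression table
whose four direction groups pass the differential filter by construction
with all other genes failing it. Defaults are the validated study
conditions: 100 bp windows, planting rate 0.5, 50 reads/peak, direction
counts (255, 183, 186, 71) in a 12,000-gene universe, and the category mix
(intron 41%, proximal promoter 12%, distal promoter 9%, downstream 8%,
coding exon 3%, 5′UTR 3%, 3′UTR 1%, distal intergenic 23%).

Not modeled: sequence composition structure (real CpG islands arise from
evolutionary processes, not i.i.d. draws), read errors and fragment-length
distributions, overlapping genes and isoform diversity, and count-level
expression noise (differential calling itself is out of scope; the table
carries already-computed fold-changes and q-values). Passing tests therefore
demonstrate correctness of the pipeline's arithmetic and bookkeeping on
inputs with known truth — not performance on real chromatin data.

## Validation experiment sizes

The planted-motif positive control runs on a 10 kb genome with 200
foreground windows, planting rate 0.5, and 20 random decoy motifs, with
thresholds calibrated from 2,000 null k-mers; 20 seeded replicates are the
reported unit. At these sizes the planted consensus occupies ~8% of the
genome, so GC-matched background windows frequently contain instances too;
the planted motif still wins the collapsed ranking in ≈ 19–20 of 20
replicates, and single-replicate failures (a lucky decoy at p ≈ 5e-3)
are expected behavior at this saturation, not defects. Statistical kernels
are checked against exact rational enumeration (complete for small tables,
seeded random draws for margins up to 30) and the classifier against a
literal rule-by-rule checker on 10,000 random regions.

## Known limitations

- Occurrence-level enrichment (counting multiple matches per window) is not
  implemented; the binary convention is fixed.
- The affinity-propagation preference is a global scalar; per-motif
  preferences are not exposed.
- BAM input is not supported; reads enter as single-base 5′ BED records.
- Multi-contig genomes are supported by the scanners and samplers but the
  synthetic generator emits one contig.
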