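# Methods

## The procedure

`rhizocomp` implements a comparative presence/absence analysis for
discovering candidate rhizome-associated genes in a de-novo-assembled
transcriptome of a rhizomatous grass. The analysis takes four sequence
inputs — focal transcript contigs, an annual relative's reference
proteome, a rhizomatous relative's reference proteome, and a
rhizome-tissue transcript assembly from that rhizomatous relative — plus
per-transcript abundance and, optionally, GO annotations. The stages
are:

1. **Coding-region gate.** Contigs are scanned for open reading frames
   in all six translation frames; a contig enters the analysis if it
   carries an ATG-initiated ORF of at least `min_orf_nt` nucleotides
   (default 297). This is a deliberately simple, length-only coding
   predictor: no Markov coding-potential score and no homology rescue.
   Within a frame, nested ORFs sharing a stop codon collapse to the
   longest (first ATG after the previous stop).
2. **Quantification and expression filter.** FPKM is computed from
   estimated fragment counts and effective lengths exactly as a
   quantifier reports them, `fpkm_i = c_i · 10⁹ / (l̃_i · N)` with `N`
   the summed estimated count. Transcripts with FPKM strictly below the
   threshold (default 1.0) are removed as probable background; a value
   exactly at the threshold survives. For synthetic reads a naive exact
   counter stands in for pseudoalignment: a read is assigned to every
   transcript containing it (or its reverse complement) as an exact
   substring, multi-mapping reads split fractionally and equally.
3. **Contamination filter.** Each query's top hit against an
   organism-labelled protein database decides its status: removed iff
   the top hit's organism is not on the plant whitelist. Queries with
   no hits are kept — absence of annotation is not evidence of
   contamination.
4. **Translated searches and partition.** Queries (full contigs,
   BLASTX-style six-frame translation — not the predicted ORFs) are
   searched against both reference proteomes at the same E-value cutoff
   (default 1e-20) and partitioned into five disjoint categories: hits
   in both, only-annual, only-rhizomatous (split by whether the top
   rhizomatous subject is evidenced as rhizome-expressed), and no hits.
   Rhizome-expression evidence is the set of reference peptides that
   are top hits of the rhizome-assembly contigs.
5. **Candidate extraction.** Candidates are the
   only-rhizomatous-with-rhizome-assembly-support pool, minus
   low-expression and contaminant contigs. The two removal filters and
   the pool intersection commute, so filter order cannot change the
   final set (asserted by a property test). The distinct top
   rhizomatous subjects of the candidates form the unique-peptide
   summary.
6. **Enrichment.** Candidate vs filtered-background GO-term 2×2 tables
   are tested with the two-sided Fisher's exact test; q-values are
   Benjamini–Hochberg across all tested terms. Terms are tested exactly
   as annotated — no GO-DAG ancestor propagation (annotation pipelines
   of the Blast2GO family emit already-propagated terms).

## Alignment engine and E-values

The homology stage is an exact Smith–Waterman local alignment
(BLOSUM62; affine gaps, open 11 / extend 1, so a gap of length *g*
costs 11 + *g*) over all query-frame × subject pairs. E-values use the
Karlin–Altschul closed form

    E = K · m · n · exp(−λ · S)

with *m* the translated frame length (aa), *n* the summed database
length (aa), and the standard gapped BLOSUM62/11,1 constants λ = 0.267,
K = 0.041; bit score = (λS − ln K)/ln 2. No composition-based or
edge-length corrections are applied. This is intentionally a desk-scale
engine: it is exact where heuristic seeded search is approximate, and at
real scale users import 12-column tabular output from an external BLASTX
run instead, which is a drop-in replacement. An optional `seeded` mode
applies a shared-4-mer prefilter (≥ 2 shared k-mers per frame-subject
pair) before the exact DP; it can only drop alignments too weak to share
two 4-mers and is meant for larger synthetic runs.

One hit is reported per (query, subject) pair — the best frame. Top-hit
ties break by minimum E-value, then lexicographic subject id; ORF-length
ties break by frame order +1,+2,+3,−1,−2,−3 then position, so every
output is deterministic.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `evalue_cutoff` | 1e-20 | significance threshold for every translated search (applied uniformly, including the rhizome-assembly search) |
| `min_fpkm` | 1.0 | expression floor; removal is strict `<` |
| `min_orf_nt` | 297 | minimum ORF length (nt, incl. stop) for the coding gate |
| `match_mode` | `top` | rhizome-assembly support = top rhizomatous subject rhizome-expressed; `any` accepts any shared subject |
| `gap_open`/`gap_extend` | 11 / 1 | affine gap penalties (BLAST convention) |
| `lambda_`, `k_` | 0.267, 0.041 | Karlin–Altschul constants for gapped BLOSUM62/11,1 |

`match_mode` exists because "shares the same hit" is ambiguous between
top-hit identity and any-hit overlap; both readings are one flag apart
and `top` is the default as the stricter, more natural reading.

## The synthetic system

The generator plants a three-taxon gene history: ancestral peptides are
drawn at random (initiator M, no internal stops), per-taxon copies are
mutated at a per-site amino-acid rate and back-translated with uniform
codon choice, then wrapped in random UTRs. Mutating at the amino-acid
level (rather than nucleotide level) makes divergence map directly onto
alignment-score decay, which is the property the E-value threshold acts
on. Six gene classes control presence/absence: core (all three taxa),
rhizome-specific (both rhizomatous lineages, absent in the annual — the
planted truth), annual-only, focal-private, contaminant (non-plant
labelled homolog in the combined database), and low-expression noise.
The noise class deliberately mimics the rhizome-specific
presence/absence profile so that only the expression filter separates it
from true candidates.

Sequencing is emulated by drawing 50–200 exact fragments per expressed
gene (uniform positions, either strand). Noise genes receive zero
fragments: at a desk-scale total of a few thousand fragments, a single
assigned fragment already implies FPKM far above 1, so a sub-threshold
planted FPKM is only realisable as 0. The planted FPKM recorded in the
truth object is the value implied by the drawn counts, and a test
verifies that re-counting the emitted fragments reproduces it within 25%
relative tolerance.

What the generator does **not** emulate — and hence what green tests do
not show about real data: read errors and quality trimming, isoforms and
fragmented/chimeric contigs, polyploidy, codon-usage bias, EM-based
multi-mapping resolution, and genuinely weak homology near the E-value
boundary. Passing the planted-truth test shows the plumbing composes
correctly under separable conditions, not that the thresholds are
optimal for any real assembly.

## Numerical and degenerate-input choices

- N50 uses exact integer arithmetic (`2 · coverage ≥ total`), returns
  the maximum qualifying length, and is undefined (error) on empty
  input. GC pools counts over all records and excludes N from the
  denominator.
- Codons containing ambiguity characters translate to `X`; stops render
  `*` and score like any BLOSUM62 `*` column if they enter an
  alignment.
- Local alignment of an empty string scores 0 by contract; characters
  outside the matrix alphabet raise.
- FPKM requires a positive total count (error otherwise); a transcript
  missing from the abundance table is treated as unexpressed and
  removed by the expression filter with a logged warning.
- Fisher's two-sided p sums all same-margin tables whose point
  probability does not exceed the observed one; degenerate margins give
  p = 1. Equal candidate/background frequencies report direction
  `none`.
- Every run directory is byte-deterministic for fixed config and
  inputs: sorted record order, fixed float formats, no timestamps in
  any output file.

## Problem sizes

The test suite and the acceptance script run the noiseless 25-gene
system (10 core, 5 rhizome-specific, 3 annual-only, 3 contaminant, 4
low-expression; ~2.8k fragments), which completes the full pipeline in
well under a minute on one CPU. The divergence sweep uses a 12-gene
system through the library API at rates 0, 0.25, 0.45. The generator's
own default scale (200 genes, mean CDS 900 nt) is intended for manual
exploration, preferably with `seeded_search` enabled.

## Known limitations

- The coding gate is length-only; it will happily call long spurious
  ORFs in repetitive sequence and miss short genuine ones (the 297 nt
  default excludes peptides under ~98 aa).
- Karlin–Altschul constants are treated as exact for the chosen scoring
  scheme; no per-query recalibration, so absolute E-values differ from
  a real BLASTX run even when relative ranking agrees.
- Single-sample FPKM semantics only: no replicates, no uncertainty on
  abundance estimates, no TPM-based filtering.
- The contamination call trusts the organism labels of the supplied
  database; there is no taxonomy service or lineage expansion behind
  the plant whitelist.
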