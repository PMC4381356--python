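# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator, and the limits of what the test suite
demonstrates.

## Bin partition

Every gene span is cut at each distinct exon start/end over all of its
transcripts, yielding intervals inside which each transcript has uniform
exon/intron status.  Internal coordinates are 0-based half-open
throughout; GFF3/GTF (1-based inclusive) and BED conventions are converted
only at file boundaries, so interval arithmetic never carries ±1 terms.

Classification: only transcripts whose span overlaps a bin vote.  A bin
exonic in all voters is an exon-bin; intronic in all, an intron-bin;
mixed, an AS-bin.  The AS subclass comes from the bases flanking the bin
in each transcript that splices it out: (intron, intron) → ES,
(exon, exon) → IR, (exon, intron) → alternative donor on the plus strand
(alternative acceptor on minus), (intron, exon) → the mirror.
Disagreement between splicing transcripts, or a flank outside a
transcript's span, gives *multiple*.  This makes the per-bin decision rule
total; nested or pathological isoform structures land in *multiple* rather
than being silently mis-assigned.

Bins overlapping a different gene (either strand) are flagged ambiguous
and excluded from counting and testing: counting is unstranded, so reads
in shared regions cannot be attributed to one gene, and exclusion avoids
double-counting.  Rare gaps in a gene span covered by no transcript are
classed as intronic.

## Counting

A read supports every non-ambiguous bin that any of its aligned, gapless
segments overlaps by ≥1 nt.  N-gapped (skipped) stretches support
nothing — a junction read contributes zero to the intron bin it spans,
which is exactly what distinguishes spliced molecules from retained ones.
Genes are counted once per read.  Unmapped, secondary, supplementary and
duplicate-flagged reads are skipped; multimappers are counted at their
primary alignment.  Counting is unstranded by default (TruSeq-style
libraries).  The gene read-density denominator is the exonic union (sum
of the gene's non-ambiguous exon- and AS-bin lengths), not the full span:
gene expression is an exonic quantity, and using the span would deflate
gene densities of intron-rich genes and inflate their Splicing Indexes.

## Exact test and dispersion

Counts are modelled NB(μ, φ) with Var = μ + φμ² and a single common φ per
analysis level (gene-level and bin-level estimated separately).  φ is
estimated by maximizing the summed conditional log-likelihood of the
replicate counts given each feature's per-group total, after scaling
counts to the geometric-mean library size and rounding; the optimum is
located on a log grid over φ ∈ [1e-6, 10] and refined by bounded scalar
minimization, with estimates below 1e-5 reported as the boundary φ = 0.

For a two-group comparison the per-group sums (S_A, S_B) of
library-equalized counts are conditioned on their total T.  For n_A and
n_B replicates with equal means, S_A | T is beta-binomial(T, n_A/φ, n_B/φ)
— the conditional of two NB sums with a common dispersion — degenerating
to Binomial(T, n_A/(n_A+n_B)) as φ → 0.  The two-sided p-value sums the
probabilities of all splits no more likely than the observed one (with a
1e-10 relative tolerance for float ties), capped at 1.  This "minimum
likelihood" rule is well defined for asymmetric conditional distributions;
it is checked against brute-force enumeration in the tests and acceptance
script.

Library equalization is a linear scaling to the geometric-mean library
size with group sums rounded to integers (the conditional test needs
integer totals).  It is exact in the equal-library case and a mild
approximation otherwise; TMM-style composition correction is deliberately
not applied, so strongly composition-biased designs should be normalized
upstream.  log2 fold changes use normalized group means with a 0.5
pseudo-count added to both groups when either mean is zero.

FDR control is Benjamini–Hochberg (statsmodels implementation,
cross-checked against an independent step-up oracle).

## Filter cascade and the altered call

Before bin-level testing (defaults in parentheses):

1. exon-bins are not tested (only AS events and intron retention are of
   interest);
2. ambiguous bins dropped;
3. bins of monoexonic genes dropped;
4. bins with mean raw count < 5 in any condition dropped;
5. bins of genes with read density ≤ 0.05 in any genotype dropped;
6. bins with SI ≤ 0.05 in both contrast genotypes dropped.

Filtering precedes testing so the BH family contains only analyzable
bins.  AS-bins and intron-bins form separate BH families and separate
report tables, since they answer different questions (shifts in annotated
events vs novel retention).

SI per genotype uses genotype-mean densities (one SI per genotype, then
one ratio), not per-replicate SIs averaged.  The altered call requires
|log2 FC| > 0.58 AND FDR < 0.15 AND |log2 SIR| > 0.58, all strict.  The
SIR guard is the load-bearing part: a pure expression change scales bin
and gene densities together, leaves SIR at 1, and is never reported as
splicing, however significant its fold change (verified on constructed
datasets with injected expression-only effects).

Gene-level expression analysis mirrors this with a mean ≥ 10 reads per
condition filter (required in *every* condition — the stricter reading
keeps low-information genes out of dispersion estimation) and calls at
|log2 FC| > 0.58, FDR < 0.10, both strict.

## Enrichment and splice-site statistics

Representation factor RF = k·N/(n₁·n₂); over-/under-representation
p-values are hypergeometric tails P(X ≥ k) / P(X ≤ k) with
X ~ Hypergeom(N, n₂, n₁).  No multiple-testing correction across
categories by default (raw p ≤ 0.05 flags significance); a BH option
exists.  The universe is caller-supplied; the natural default is the
expression-filtered gene set, but a whole-genome universe is equally
expressible.

Splice-site analysis selects intron-retention records changed at least
two-fold (|log2 SIR| ≥ 1) at FDR ≤ 0.1, maps them to their enclosing
annotated introns, and extracts strand-corrected windows: donor = 3 exonic
+ 10 intronic nt (positions −3..−1, +1..+10), acceptor mirrored.  The
background is every annotated intron with GT..AG terminal dinucleotides
(the major-spliceosome class; rare U12-type GT-AG introns are not
distinguished).  Per position × nucleotide cell: RF = foreground
frequency / background frequency, with a hypergeometric p for drawing the
n foreground sites from the background pool, over or under tail chosen by
RF ≷ 1.  N bases are excluded from denominators.

## Synthetic data

The generator emulates the structure the analysis assumes, with known
ground truth:

* **Genome/annotation** — 300 genes by default (3–4 exons of 100–220 nt,
  introns of 100–250 nt, 200 nt intergenic), alternating strand, each
  intron GT..AG with donor windows drawn from a configurable per-position
  nucleotide model (plant-like consensus by default; arbitrary depletions
  for the site-statistics experiments).  8% of genes each carry an
  annotated ES, IR, alternative-donor or alternative-acceptor second
  isoform; alternative sites get GT/AG motifs planted so every isoform's
  introns remain canonical.
* **Counts** — per gene, the expected total is Σ_bins depth × length ×
  inclusion, where inclusion is 1 for constitutive exons, the isoform
  share (0.5) for AS bins, and the pre-mRNA retention fraction (0.15
  baseline) for intron bins.  Per replicate the gene total is NB(μ, φ =
  0.1) and is split multinomially across bins — this preserves the
  dispersion exactly at the bin level (Var X = μ_b + φμ_b² under NB-total
  + multinomial thinning), so bin-level tests see the same φ as gene-level
  ones.  Depth is calibrated so the *analyzed* (intron/AS) bins average
  ~50 reads, with a lognormal spread (σ = 0.4) across genes.
* **Effects** — expression shifts multiply mutant depth; intron-retention
  gains and isoform-usage shifts are solved numerically (Brent root
  finding on the generative expectation) so that the *realized* expected
  log2 SIR equals the target exactly, including the gene-density shift
  that the extra intron reads themselves cause.  Targets that would need
  retention above ~1 raise an error naming the event.
* **Reads** — sampled uniformly along each source molecule (annotated
  isoforms plus single-intron-retained pre-mRNA variants), written as
  sorted indexed BAM with M/N CIGARs, together with the generator's own
  per-bin overlap tally for exact self-consistency checks of the counter.

What the generator does **not** model: sequencing errors, positional or
fragment-length bias, stranded protocols, multimapping ambiguity,
overlapping genes (available but off by default), joint retention of
several introns in one molecule, and isoform-specific expression noise.
Passing tests therefore demonstrate correctness of the partition,
counting and inference machinery under the stated NB model — not
robustness to alignment artifacts or biases of real libraries.

## Benchmark conditions and runtimes

The recovery benchmark uses 300 genes, 3 wt vs 3 mutant replicates,
φ = 0.1, ~50 reads per analyzed bin, and 30 injected intron-retention
gains at log2 SIR = 1.5, averaged over 5 seeds; null calibration uses
Poisson data with 2,000 features.  These desk-scale sizes keep the whole
suite and the acceptance script in the seconds-to-a-minute range while
leaving the per-feature statistics at realistic depths.

## Numerical and degenerate-input choices

* p-values are computed in log space via log-gamma and exponentiated once;
  ties in the minimum-likelihood rule use a 1e-10 relative tolerance.
* Both groups all-zero → p = 1, log2 FC = 0 by convention.
* SI with zero gene density is undefined (NaN) and the record is excluded
  before testing; SIR with either SI ≤ 0 likewise.
* Zero-length features are an error; zero-depth samples are retained with
  a warning and a guard library size of 1.
* All randomness flows from a single integer seed; identical inputs and
  seed give byte-identical outputs (checked for the generator, the
  partition and the full run-all pipeline).

## Known limitations

* Exact replication of results computed with other NB machinery (e.g.
  different normalization or tagwise dispersion) is not claimed; the
  common-dispersion exact test is the simplest member of that family.
* The library-equalization approximation degrades under strong
  composition bias between groups.
* The *multiple* event class is a catch-all; no attempt is made to
  decompose composite regions into elementary events.
* Annotation-derived bins only: unannotated junctions or novel exons are
  invisible by design.
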