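# binsplice

Bin-based differential gene expression and alternative-splicing analysis
for bulk RNA-seq, with a focus on detecting **intron retention in
constitutive introns** — splicing changes invisible to methods that only
look at annotated alternative events.

## Who this is for

Groups studying splicing regulators (spliceosome components, RNA-binding
proteins, chromatin modifiers such as protein arginine methyltransferases)
who compare mutant and wild-type transcriptomes and need to separate true
splicing changes from expression changes, in organisms like *Arabidopsis
thaliana* where intron retention is the dominant alternative-splicing mode.

## The model

The annotation is flattened per gene into disjoint **bins**: the gene span
is cut at every exon boundary of every isoform, so inside a bin every
isoform has uniform exon/intron status.  A bin exonic in all isoforms is an
*exon-bin*, intronic in all an *intron-bin*, and mixed an *AS-bin*,
subclassified by the flanking-base topology of the isoforms that splice it
out: exon skipping (ES), alternative donor (alt5) or acceptor (alt3),
annotated intron retention (IR), or *multiple* when isoforms disagree.
Unlike exon-centric flattening, intron-bins are first-class: retention of
a "constitutive" intron shows up as signal in its intron-bin.

Reads are counted per bin (a read supports every bin one of its aligned
segments overlaps; N-gapped junction stretches support nothing) and per
gene.  For a feature of length *L* with count *n*, the read density is
*n/L*, and for bin *b* of gene *g* in genotype *t*:

    SI_t(b)  = density_t(b) / density_t(g)            (Splicing Index)
    SIR(b)   = SI_mut(b) / SI_wt(b)                   (Splicing Index Ratio)

Counts are modelled as negative binomial with a common dispersion φ
(Var = μ + φμ²) estimated by conditional maximum likelihood; each feature
gets an exact conditional test of the split of its total between the two
genotypes (beta-binomial conditional; the conditional binomial when φ = 0),
with Benjamini–Hochberg FDR control.

A bin is called **altered** only if all three hold (defaults shown;
intron-bins and AS-bins are corrected and reported as separate families):

* |log2 FC| > 0.58 (bin abundance, mutant/wild type),
* FDR < 0.15,
* |log2 SIR| > 0.58 — the guard that rejects expression-driven changes.

Gene-level differential expression uses the same exact test with a
10-reads-per-condition filter and calls at |log2 FC| > 0.58, FDR < 0.10.
Gene-list enrichment uses the representation factor RF = k·N/(n₁·n₂)
(observed over expected overlap) with hypergeometric tail p-values, and
the splice-site module compares position-wise nucleotide frequencies of
donor/acceptor windows of affected introns against the genome-wide GT..AG
intron background with per-cell RF and hypergeometric p.

## Worked example

All inputs can be simulated with known ground truth (the `synthetic_data`
module is a tested, first-class part of the package):

```python
from binsplice.synthetic_data import simulate_dataset
from binsplice.splicing_pipeline import differential_splicing, split_reports

ds = simulate_dataset(seed=42)          # 300 genes, 3 wt vs 3 mut, phi=0.1,
                                        # 30 IR gains injected at log2 SIR = 1.5
records = differential_splicing(ds.binset, ds.bin_table, ds.gene_table,
                                ("wt", "mut"))
as_tab, ir_tab = split_reports(records)
```

This prints (seed 42):

```
bin census: {'total': 1860, 'exon': 1032, 'intron': 732, 'AS': 96, ...}
tested: 96 AS bins, 732 intron bins
altered intron-retention bins: 23
          gene_id  SI_wt  SI_mut  log2FC  log2SIR    FDR
G0096:002   G0096  0.140   0.386   1.695    1.462  0.002
G0103:002   G0103  0.112   0.395   1.898    1.816  0.001
G0106:002   G0106  0.138   0.373   1.664    1.431  0.002
G0109:002   G0109  0.155   0.380   1.345    1.297  0.038
G0127:002   G0127  0.143   0.383   1.643    1.418  0.003
recovered 23 of 30 injected IR gains
```

Reading the first row: in gene G0096 the intron-bin G0096:002 carries 14%
of the gene's read density in wild type but 39% in the mutant — a 2.8-fold
(log2 SIR 1.46) relative increase in retention at FDR 0.002, while the
gene's own expression is unchanged.

The same pipeline is available from the shell:

```bash
binsplice simulate --seed 42 --out sim/ --reads
binsplice count    --annotation sim/annotation.gff3 --design sim/design.tsv \
                   --out-dir counts/
binsplice splicing --counts-dir counts/ --annotation sim/annotation.gff3 \
                   --contrast wt,mut --out-dir splicing/
binsplice splicesites --records splicing/intron_retention.tsv \
                   --annotation sim/annotation.gff3 --genome sim/genome.fa \
                   --out-prefix sites
```

or end-to-end via `binsplice run-all --config run.yaml` (see
`docs/methods.md` for the config keys and every threshold).

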