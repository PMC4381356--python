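"""Per-bin and per-gene read counting from coordinate-sorted BAM files.

A read is assigned to every non-ambiguous bin that any of its aligned
(gapless) segments overlaps by at least one nucleotide; N-gapped (skipped)
stretches create no overlap, so a junction read spanning an intron bin
contributes nothing to that bin.  A gene is counted once per read that hits
any of its bins.  Counting is unstranded by default (TruSeq-style
libraries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from binsplice.annotation_binning import BinSet

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Feature x sample integer read counts with design and lengths."""

    counts: pd.DataFrame  # index: feature_id, columns: sample_id
    design: pd.DataFrame  # columns: sample_id, genotype, replicate
    feature_lengths: pd.Series  # index: feature_id, nt
    library_sizes: pd.Series = field(default=None)  # per sample

    def __post_init__(self) -> None:
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if not set(self.counts.columns) <= set(self.design["sample_id"]):
            raise ValueError("count columns missing from design")
        missing = set(self.counts.index) - set(self.feature_lengths.index)
        if missing:
            raise ValueError(f"{len(missing)} features lack lengths")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def genotype_of(self, sample_id: str) -> str:
        row = self.design.loc[self.design["sample_id"] == sample_id]
        return row["genotype"].iloc[0]

    def samples_of(self, genotype: str) -> list[str]:
        ids = self.design.loc[self.design["genotype"] == genotype, "sample_id"]
        return [s for s in self.counts.columns if s in set(ids)]

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")


@dataclass
class DensityTable:
    """Per-sample and per-genotype read densities (reads per nt)."""

    density: pd.DataFrame  # feature x sample
    genotype_mean: pd.DataFrame  # feature x genotype


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a design TSV: sample_id, bam_path, genotype, replicate."""
    design = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "replicate"}
    if not required <= set(design.columns):
        raise ValueError(f"design table needs columns {sorted(required)}")
    return design


def _bin_trees(binset: BinSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, b in enumerate(binset.bins):
        if b.ambiguous:
            continue
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, i)
    return trees


def gene_exonic_lengths(binset: BinSet) -> pd.Series:
    """Exonic-union length per gene: sum of its non-ambiguous exon and AS
    bins.  This is the denominator of the gene read density."""
    acc: dict[str, int] = {}
    for b in binset.bins:
        if b.ambiguous or b.kind == "intron":
            continue
        acc[b.gene_id] = acc.get(b.gene_id, 0) + b.length
    return pd.Series(acc, dtype=float)


def count_reads(
    bam_paths: dict[str, str | Path],
    binset: BinSet,
    design: pd.DataFrame,
) -> tuple[CountTable, CountTable]:
    """Count reads per bin and per gene for each sample's BAM.

    ``bam_paths`` maps sample_id -> BAM path (sorted + indexed).  Unmapped,
    secondary, supplementary and duplicate-flagged reads are skipped.
    Returns ``(bin_table, gene_table)``; library size is the number of reads
    assigned to at least one bin.
    """
    import pysam

    trees = _bin_trees(binset)
    bins = binset.bins
    bin_ids = [b.bin_id for b in bins]
    gene_ids = sorted({b.gene_id for b in bins})
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    samples = list(bam_paths)
    bin_counts = np.zeros((len(bins), len(samples)), dtype=np.int64)
    gene_counts = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    lib_sizes = np.zeros(len(samples), dtype=np.int64)

    for j, sample in enumerate(samples):
        path = Path(bam_paths[sample])
        if not path.with_suffix(path.suffix + ".bai").exists() and not Path(
            str(path) + ".bai"
        ).exists():
            raise FileNotFoundError(f"missing BAM index for {path}")
        with pysam.AlignmentFile(str(path), "rb") as bam:
            refs = set(bam.references)
            unknown = refs - set(trees)
            if unknown:
                logger.warning(
                    "%s: contigs absent from annotation ignored: %s",
                    path, ", ".join(sorted(unknown)[:5]),
                )
            for read in bam.fetch(until_eof=True):
                if (read.is_unmapped or read.is_secondary
                        or read.is_supplementary or read.is_duplicate):
                    continue
                tree = trees.get(read.reference_name)
                if tree is None:
                    continue
                hit_bins: set[int] = set()
                for s, e in read.get_blocks():
                    for iv in tree.overlap(s, e):
                        hit_bins.add(iv.data)
                if not hit_bins:
                    continue
                lib_sizes[j] += 1
                hit_genes = set()
                for bi in hit_bins:
                    bin_counts[bi, j] += 1
                    hit_genes.add(bins[bi].gene_id)
                for g in hit_genes:
                    gene_counts[gene_pos[g], j] += 1
        if lib_sizes[j] == 0:
            logger.warning("%s: no assignable reads (empty library)", path)

    design = design[design["sample_id"].isin(samples)].reset_index(drop=True)
    lib = pd.Series(lib_sizes, index=samples, dtype=float)
    bin_table = CountTable(
        counts=pd.DataFrame(bin_counts, index=bin_ids, columns=samples),
        design=design,
        feature_lengths=pd.Series({b.bin_id: float(b.length) for b in bins}),
        library_sizes=lib,
    )
    glen = gene_exonic_lengths(binset)
    glen = glen.reindex(gene_ids).fillna(
        pd.Series({g: sum(b.length for b in binset.gene_bins(g)) for g in gene_ids})
    )
    gene_table = CountTable(
        counts=pd.DataFrame(gene_counts, index=gene_ids, columns=samples),
        design=design,
        feature_lengths=glen,
        library_sizes=lib,
    )
    return bin_table, gene_table


def read_density(table: CountTable) -> DensityTable:
    """Read density = count / feature length, plus per-genotype means."""
    lengths = table.feature_lengths.reindex(table.counts.index)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    dens = table.counts.div(lengths, axis=0)
    by_geno = {}
    for geno in table.design["genotype"].unique():
        cols = table.samples_of(geno)
        if cols:
            by_geno[geno] = dens[cols].mean(axis=1)
    return DensityTable(density=dens, genotype_mean=pd.DataFrame(by_geno))
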