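"""Bin-level differential splicing via Splicing Index Ratio.

For each intron or AS bin the Splicing Index (SI) is the bin read density
divided by its gene's read density, computed per genotype from
genotype-mean densities.  The Splicing Index Ratio (SIR) is SI in the
mutant over SI in the wild type; it cancels gene-level expression changes,
so a bin is called altered only when the bin-level fold change, its FDR and
|log2 SIR| all clear their thresholds (defaults 0.58 / 0.15 / 0.58).

Intron bins (novel intron retention in constitutive introns) and AS bins
(annotated alternative-splicing regions) are tested and BH-adjusted as
separate families and reported in separate tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from binsplice.annotation_binning import BinSet
from binsplice.bam_counting import CountTable, read_density
from binsplice.count_statistics import (
    bh_adjust,
    estimate_common_dispersion,
    exact_test_table,
)


@dataclass(frozen=True)
class SplicingThresholds:
    log2_fc: float = 0.58
    fdr: float = 0.15
    log2_sir: float = 0.58
    min_mean_count: float = 5.0
    min_gene_density: float = 0.05
    min_si: float = 0.05


def splicing_index(bin_density: float, gene_density: float):
    """SI = bin density / gene density; NaN when the gene density is 0
    (the record is excluded downstream)."""
    if bin_density < 0 or gene_density < 0:
        raise ValueError("densities must be non-negative")
    if gene_density == 0:
        return np.nan
    return bin_density / gene_density


def splicing_index_ratio(si_mut: float, si_wt: float):
    """log2(SI_mut / SI_wt); NaN when either SI is zero or undefined."""
    if not (si_mut > 0 and si_wt > 0):
        return np.nan
    return float(np.log2(si_mut / si_wt))


def filter_bins(
    binset: BinSet,
    bin_table: CountTable,
    gene_table: CountTable,
    contrast: tuple[str, str],
    thresholds: SplicingThresholds = SplicingThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the filter cascade; return per-bin annotations for the bins
    that survive, plus removal tallies per rule.

    Rules, in order: non-testable kind (exon bins are not tested), ambiguous
    bins, bins of monoexonic genes, mean raw count < min in any condition,
    gene read density <= min in any genotype, SI <= min in both contrast
    genotypes (SI undefined counts as failing).
    """
    meta = binset.to_frame().set_index("bin_id")
    meta = meta.loc[bin_table.counts.index]
    genotypes = list(bin_table.design["genotype"].unique())

    bin_dens = read_density(bin_table)
    gene_dens = read_density(gene_table)

    tallies: dict[str, int] = {}
    keep = meta["kind"].isin(["intron", "AS"])
    tallies["exon_bins"] = int((~keep).sum())

    amb = keep & meta["ambiguous"].astype(bool)
    tallies["ambiguous"] = int(amb.sum())
    keep &= ~meta["ambiguous"].astype(bool)

    mono = keep & meta["gene_id"].isin(binset.monoexonic_genes)
    tallies["monoexonic"] = int(mono.sum())
    keep &= ~mono

    low = pd.Series(False, index=meta.index)
    for geno in genotypes:
        cols = bin_table.samples_of(geno)
        low |= bin_table.counts[cols].mean(axis=1) < thresholds.min_mean_count
    tallies["low_count"] = int((keep & low).sum())
    keep &= ~low

    gmean = gene_dens.genotype_mean
    gene_ok = (gmean[genotypes] > thresholds.min_gene_density).all(axis=1)
    bin_gene_ok = meta["gene_id"].map(gene_ok).fillna(False).astype(bool)
    tallies["low_gene_density"] = int((keep & ~bin_gene_ok).sum())
    keep &= bin_gene_ok

    # SI per contrast genotype from genotype-mean densities
    si = {}
    for geno in contrast:
        gd = meta["gene_id"].map(gene_dens.genotype_mean[geno])
        with np.errstate(divide="ignore", invalid="ignore"):
            s = bin_dens.genotype_mean[geno] / gd
        si[geno] = s.replace([np.inf, -np.inf], np.nan)
    si_frame = pd.DataFrame(si)
    si_ok = (si_frame > thresholds.min_si).any(axis=1)
    tallies["low_si"] = int((keep & ~si_ok).sum())
    keep &= si_ok

    out = meta.loc[keep, ["gene_id", "kind", "event_class"]].copy()
    for geno in contrast:
        out[f"SI_{geno}"] = si_frame.loc[keep, geno]
    tallies["retained"] = int(keep.sum())
    return out, tallies


def differential_splicing(
    binset: BinSet,
    bin_table: CountTable,
    gene_table: CountTable,
    contrast: tuple[str, str],
    thresholds: SplicingThresholds = SplicingThresholds(),
    phi: float | None = None,
) -> pd.DataFrame:
    """Exact test per retained bin with the three-way altered call.

    ``contrast = (wild_type, mutant)``.  Returns one row per retained bin:
    SI per genotype, log2FC of bin abundance (mutant over wild type, from
    library-equalized counts), log2 SIR, p, FDR (BH within the intron and
    AS families separately) and the final call.
    """
    wt, mut = contrast
    genotypes = set(bin_table.design["genotype"])
    if not {wt, mut} <= genotypes:
        raise ValueError(f"contrast {contrast} not in design genotypes")
    retained, _ = filter_bins(binset, bin_table, gene_table, contrast, thresholds)
    if retained.empty:
        return retained.assign(log2FC=[], log2SIR=[], pvalue=[], FDR=[], call=[])

    cols_a = bin_table.samples_of(wt)
    cols_b = bin_table.samples_of(mut)
    counts = bin_table.counts.loc[retained.index]
    lib_a = bin_table.library_sizes[cols_a].to_numpy(dtype=float)
    lib_b = bin_table.library_sizes[cols_b].to_numpy(dtype=float)
    counts_a = counts[cols_a].to_numpy(dtype=float)
    counts_b = counts[cols_b].to_numpy(dtype=float)

    if phi is None:
        both = np.hstack([counts_a, counts_b])
        groups = np.array([wt] * len(cols_a) + [mut] * len(cols_b))
        libs = np.concatenate([lib_a, lib_b])
        phi = estimate_common_dispersion(both, groups, libs).phi

    lfc, p = exact_test_table(counts_a, counts_b, phi, lib_a, lib_b)
    res = retained.copy()
    res["log2FC"] = lfc
    res["log2SIR"] = [
        splicing_index_ratio(m, w)
        for m, w in zip(res[f"SI_{mut}"], res[f"SI_{wt}"])
    ]
    res["pvalue"] = p

    # BH within intron and AS families separately
    res["FDR"] = np.nan
    for kind in ("intron", "AS"):
        mask = res["kind"] == kind
        if mask.any():
            res.loc[mask, "FDR"] = bh_adjust(res.loc[mask, "pvalue"])

    altered = (
        (res["log2FC"].abs() > thresholds.log2_fc)
        & (res["FDR"] < thresholds.fdr)
        & (res["log2SIR"].abs() > thresholds.log2_sir)
        & res["log2SIR"].notna()
    )
    res["call"] = np.where(altered, "altered", "not_altered")
    return res


def split_reports(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(AS-events table, intron-retention table)."""
    return (records[records["kind"] == "AS"].copy(),
            records[records["kind"] == "intron"].copy())


def event_category_breakdown(records: pd.DataFrame) -> pd.DataFrame:
    """Tally altered bins by event class and direction of the SIR."""
    altered = records[records["call"] == "altered"]
    if altered.empty:
        return pd.DataFrame(columns=["event_class", "direction", "n"])
    direction = np.where(altered["log2SIR"] > 0, "+", "-")
    cls = np.where(altered["kind"] == "intron", "IR(novel)",
                   altered["event_class"])
    tab = (
        pd.DataFrame({"event_class": cls, "direction": direction})
        .value_counts()
        .rename("n")
        .reset_index()
        .sort_values(["event_class", "direction"], ignore_index=True)
    )
    return tab
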