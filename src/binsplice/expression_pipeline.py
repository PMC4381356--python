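"""Gene-level differential expression with expression filtering and
cross-genotype overlap bookkeeping.

Genes averaging fewer than ``min_mean`` raw reads in any condition are
discarded before testing; the retained genes get a common-dispersion exact
test and BH adjustment, and calls use strict thresholds |log2FC| > 0.58 and
FDR < 0.10 (both configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from binsplice.bam_counting import CountTable
from binsplice.count_statistics import (
    bh_adjust,
    estimate_common_dispersion,
    exact_test_table,
)


@dataclass(frozen=True)
class DEThresholds:
    log2_fc: float = 0.58
    fdr: float = 0.10
    min_mean: float = 10.0


def filter_expressed(
    table: CountTable, min_mean: float = 10.0
) -> tuple[list[str], dict[str, int]]:
    """Genes whose mean raw count is >= min_mean in every condition.

    Returns the retained feature ids and a {retained, discarded} tally.
    """
    genotypes = table.design["genotype"].unique()
    keep = pd.Series(True, index=table.counts.index)
    for geno in genotypes:
        cols = table.samples_of(geno)
        if not cols:
            raise ValueError(f"condition {geno!r} has no samples")
        keep &= table.counts[cols].mean(axis=1) >= min_mean
    retained = list(table.counts.index[keep])
    return retained, {"retained": len(retained),
                      "discarded": int((~keep).sum())}


def differential_expression(
    table: CountTable,
    contrast: tuple[str, str],
    thresholds: DEThresholds = DEThresholds(),
    phi: float | None = None,
) -> pd.DataFrame:
    """Exact-test DE between ``contrast = (reference, alternative)``.

    Dispersion is estimated once across all retained genes unless ``phi`` is
    given.  Returns a frame with baseMean per group, log2FC (alternative
    over reference), p, FDR and a call in {up, down, unchanged}.
    """
    ref, alt = contrast
    genotypes = set(table.design["genotype"])
    for g in contrast:
        if g not in genotypes:
            raise ValueError(f"genotype {g!r} not in design")
    retained, _ = filter_expressed(table, thresholds.min_mean)
    cols_a = table.samples_of(ref)
    cols_b = table.samples_of(alt)
    sub = table.counts.loc[retained]
    counts_a = sub[cols_a].to_numpy(dtype=float)
    counts_b = sub[cols_b].to_numpy(dtype=float)
    lib_a = table.library_sizes[cols_a].to_numpy(dtype=float)
    lib_b = table.library_sizes[cols_b].to_numpy(dtype=float)

    if phi is None:
        both = np.hstack([counts_a, counts_b])
        groups = np.array([ref] * len(cols_a) + [alt] * len(cols_b))
        libs = np.concatenate([lib_a, lib_b])
        phi = estimate_common_dispersion(both, groups, libs).phi

    lfc, p = exact_test_table(counts_a, counts_b, phi, lib_a, lib_b)
    fdr = bh_adjust(p)
    call = np.where(
        (fdr < thresholds.fdr) & (lfc > thresholds.log2_fc), "up",
        np.where((fdr < thresholds.fdr) & (lfc < -thresholds.log2_fc),
                 "down", "unchanged"),
    )
    return pd.DataFrame(
        {
            "gene_id": retained,
            f"baseMean_{ref}": counts_a.mean(axis=1),
            f"baseMean_{alt}": counts_b.mean(axis=1),
            "log2FC": lfc,
            "pvalue": p,
            "FDR": fdr,
            "call": call,
        }
    ).set_index("gene_id")


def overlap_sets(
    up_a: set[str], down_a: set[str], up_b: set[str], down_b: set[str]
) -> dict[str, int]:
    """Concordant and antagonistic overlaps between two DE call sets."""
    return {
        "up_A": len(up_a),
        "down_A": len(down_a),
        "up_B": len(up_b),
        "down_B": len(down_b),
        "common_up": len(up_a & up_b),
        "common_down": len(down_a & down_b),
        "antagonistic": len(up_a & down_b) + len(down_a & up_b),
    }


def calls_to_sets(de: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(up, down) gene-id sets from a differential_expression frame."""
    return (set(de.index[de["call"] == "up"]),
            set(de.index[de["call"] == "down"]))
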