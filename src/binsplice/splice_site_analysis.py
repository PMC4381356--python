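"""Donor/acceptor splice-site sequence statistics for intron-retention events.

Windows around splice sites are extracted strand-corrected from the genome
(position -k = exonic, +k = intronic, so +1/+2 of a GT-AG donor are G,T),
tabulated into position x nucleotide frequency matrices, and each cell is
compared with the genome-wide intron background by a representation factor
(foreground frequency over background frequency) with a hypergeometric
p-value for drawing the foreground sites from the background pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

NUCS = ("A", "C", "G", "T")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SiteWindowSet:
    """Equal-length, strand-corrected splice-site windows."""

    site_type: str  # donor | acceptor
    up: int  # exonic nt
    down: int  # intronic nt
    sequences: list[str]

    def __post_init__(self) -> None:
        if self.site_type not in {"donor", "acceptor"}:
            raise ValueError("site_type must be donor or acceptor")
        width = self.up + self.down
        for s in self.sequences:
            if len(s) != width:
                raise ValueError("window length mismatch")

    @property
    def positions(self) -> list[int]:
        """Position labels; negative = exonic side, positive = intronic."""
        if self.site_type == "donor":
            return list(range(-self.up, 0)) + list(range(1, self.down + 1))
        return list(range(-self.down, 0)) + list(range(1, self.up + 1))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, s in enumerate(self.sequences):
                fh.write(f">{self.site_type}_{i}\n{s}\n")


@dataclass
class SiteMatrix:
    """Per-position nucleotide counts/frequencies with RF and p vs background."""

    positions: list[int]
    fg_counts: pd.DataFrame  # positions x ACGT
    bg_counts: pd.DataFrame
    fg_freq: pd.DataFrame
    bg_freq: pd.DataFrame
    rf: pd.DataFrame
    p: pd.DataFrame  # tail chosen by rf vs 1 (over if rf >= 1 else under)


def select_top_events(
    records: pd.DataFrame, fold: float = 2.0, fdr: float = 0.1
) -> pd.DataFrame:
    """Intron-retention records changed at least ``fold``-fold
    (|log2 SIR| >= log2(fold)) at FDR <= ``fdr``."""
    sel = records[
        (records["kind"] == "intron")
        & (records["log2SIR"].abs() >= np.log2(fold))
        & (records["FDR"] <= fdr)
    ]
    return sel.copy()


def partition_events(ids_a: set[str], ids_b: set[str]) -> dict[str, set[str]]:
    """A-only / B-only / both partition of two selected-event id sets."""
    return {
        "A_only": ids_a - ids_b,
        "B_only": ids_b - ids_a,
        "both": ids_a & ids_b,
    }


def _fetch(genome, chrom: str, start: int, end: int) -> str | None:
    if start < 0 or end > len(genome[chrom]):
        return None
    return str(genome[chrom][start:end]).upper()


def extract_windows(
    genome,
    introns: list[tuple[str, int, int, str]],
    site_type: str,
    up: int = 3,
    down: int = 10,
) -> SiteWindowSet:
    """Extract splice-site windows for introns (chrom, start, end, strand),
    0-based half-open.

    Donor = 5' end of the intron (``up`` exonic nt then ``down`` intronic);
    acceptor = 3' end (``down`` intronic then ``up`` exonic).  Minus-strand
    introns are reverse-complemented so all windows read 5'->3' on the
    transcript.  Windows running off the contig are skipped with a warning.
    """
    import pyfaidx

    if isinstance(genome, (str, Path)):
        genome = pyfaidx.Fasta(str(genome))
    seqs = []
    for chrom, s, e, strand in introns:
        if site_type == "donor":
            if strand == "+":
                seq = _fetch(genome, chrom, s - up, s + down)
            else:
                seq = _fetch(genome, chrom, e - down, e + up)
                seq = revcomp(seq) if seq is not None else None
        else:  # acceptor
            if strand == "+":
                seq = _fetch(genome, chrom, e - down, e + up)
            else:
                seq = _fetch(genome, chrom, s - up, s + down)
                seq = revcomp(seq) if seq is not None else None
        if seq is None:
            logger.warning("window off contig for intron %s:%d-%d(%s); skipped",
                           chrom, s, e, strand)
            continue
        seqs.append(seq)
    return SiteWindowSet(site_type=site_type, up=up, down=down, sequences=seqs)


def _count_matrix(windows: SiteWindowSet) -> pd.DataFrame:
    arr = np.frombuffer("".join(windows.sequences).encode(), dtype="S1")
    arr = arr.reshape(len(windows.sequences), -1)
    counts = pd.DataFrame(0, index=windows.positions, columns=list(NUCS))
    for nuc in NUCS:
        counts[nuc] = (arr == nuc.encode()).sum(axis=0)
    return counts


def site_matrix(foreground: SiteWindowSet, background: SiteWindowSet) -> SiteMatrix:
    """Position frequency matrices with per-cell RF and hypergeometric p.

    RF = foreground frequency / background frequency.  p models drawing the
    n foreground sites from the background pool: X ~ Hypergeom(N_bg, K_bg,
    n_fg) with the over tail P(X >= k) when RF >= 1, else the under tail
    P(X <= k).  N bases are excluded from all denominators.
    """
    if not foreground.sequences:
        raise ValueError("empty foreground window set")
    if (foreground.positions != background.positions
            or foreground.site_type != background.site_type):
        raise ValueError("foreground and background windows are incompatible")
    fg = _count_matrix(foreground)
    bg = _count_matrix(background)
    fg_tot = fg.sum(axis=1)  # non-N per position
    bg_tot = bg.sum(axis=1)
    fg_freq = fg.div(fg_tot, axis=0)
    bg_freq = bg.div(bg_tot, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = fg_freq / bg_freq
    p = pd.DataFrame(1.0, index=fg.index, columns=fg.columns)
    for pos in fg.index:
        N = int(bg_tot[pos])
        n = int(fg_tot[pos])
        for nuc in NUCS:
            K = int(bg.loc[pos, nuc])
            k = int(fg.loc[pos, nuc])
            if N == 0 or n == 0:
                continue
            r = rf.loc[pos, nuc]
            if np.isnan(r) or r >= 1:
                p.loc[pos, nuc] = float(hypergeom.sf(k - 1, N, K, n))
            else:
                p.loc[pos, nuc] = float(hypergeom.cdf(k, N, K, n))
    return SiteMatrix(
        positions=list(fg.index), fg_counts=fg, bg_counts=bg,
        fg_freq=fg_freq, bg_freq=bg_freq, rf=rf, p=p,
    )


def gtag_introns(genes, genome) -> list[tuple[str, int, int, str]]:
    """All annotated introns whose terminal dinucleotides are GT...AG
    (major-spliceosome consensus), strand-aware; the genome-wide background
    set for :func:`site_matrix`."""
    import pyfaidx

    if isinstance(genome, (str, Path)):
        genome = pyfaidx.Fasta(str(genome))
    out = []
    for gene in genes:
        for s, e in gene.introns():
            if e - s < 4:
                continue
            seq = _fetch(genome, gene.chrom, s, e)
            if seq is None:
                continue
            if gene.strand == "-":
                seq = revcomp(seq)
            if seq.startswith("GT") and seq.endswith("AG"):
                out.append((gene.chrom, s, e, gene.strand))
    return out


def introns_for_bins(genes, binset, bin_ids) -> list[tuple[str, int, int, str]]:
    """Map intron-retention bins to their enclosing annotated introns
    (chrom, start, end, strand), deduplicated in input order."""
    by_id = {g.gene_id: g for g in genes}
    bin_by_id = {b.bin_id: b for b in binset.bins}
    out: list[tuple[str, int, int, str]] = []
    seen = set()
    for bid in bin_ids:
        b = bin_by_id.get(bid)
        if b is None:
            continue
        gene = by_id.get(b.gene_id)
        if gene is None:
            continue
        for s, e in gene.introns():
            if s <= b.start and b.end <= e:
                key = (gene.chrom, s, e, gene.strand)
                if key not in seen:
                    seen.add(key)
                    out.append(key)
                break
    return out


def matrix_to_tsv(matrix: SiteMatrix, prefix: str | Path) -> None:
    """Write freq/rf/p tables as <prefix>.{freq,rf,p}.tsv."""
    prefix = str(prefix)
    matrix.fg_freq.to_csv(f"{prefix}.freq.tsv", sep="\t", index_label="position")
    matrix.rf.to_csv(f"{prefix}.rf.tsv", sep="\t", index_label="position")
    matrix.p.to_csv(f"{prefix}.p.tsv", sep="\t", index_label="position")
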