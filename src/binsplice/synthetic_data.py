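"""Self-contained synthetic data with known ground truth.

Generates a small genome with multi-isoform genes (exon skipping, annotated
intron retention, alternative donor/acceptor structures), GT..AG introns
whose donor windows follow a configurable per-position nucleotide model,
negative-binomial replicate counts with common dispersion, and optionally
aligned reads — everything the pipeline consumes, with the injected
effects' expected log2 Splicing Index Ratios known exactly.

The count model: a gene's expected read total is the sum over its bins of
``depth * bin_length * inclusion``, where inclusion is the fraction of the
gene's transcript molecules in which the bin is exonic (1 for constitutive
exons, the isoform share for AS bins, the pre-mRNA retention fraction for
intron bins).  Per replicate the gene total is NB(mu, phi) and is split
multinomially across bins, which leaves the per-bin dispersion equal to phi.
Injected effects (expression shifts, intron-retention gains, isoform-usage
shifts) are solved numerically so that the *realized* expected log2 SIR —
including the gene-density shift that extra intron reads cause — hits the
requested target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from binsplice.annotation_binning import (
    Bin,
    BinSet,
    GeneModel,
    partition_transcriptome,
)
from binsplice.bam_counting import CountTable, gene_exonic_lengths
from binsplice.splice_site_analysis import SiteWindowSet, revcomp

logger = logging.getLogger(__name__)

NUCS = "ACGT"


# ---------------------------------------------------------------------------
# configuration


def default_donor_model(up: int = 3, down: int = 10) -> dict[int, dict[str, float]]:
    """Plant-like donor-site nucleotide model: invariant GT at +1/+2, strong
    A/G consensus around the boundary, mildly informative elsewhere."""
    flat = {"A": 0.28, "C": 0.17, "G": 0.17, "T": 0.38}  # intron-like
    exon_flat = {"A": 0.3, "C": 0.2, "G": 0.25, "T": 0.25}
    model = {
        -3: {"A": 0.45, "C": 0.30, "G": 0.12, "T": 0.13},
        -2: {"A": 0.60, "C": 0.10, "G": 0.18, "T": 0.12},
        -1: {"A": 0.10, "C": 0.05, "G": 0.78, "T": 0.07},
        1: {"A": 0.0, "C": 0.0, "G": 1.0, "T": 0.0},
        2: {"A": 0.0, "C": 0.0, "G": 0.0, "T": 1.0},
        3: {"A": 0.58, "C": 0.10, "G": 0.18, "T": 0.14},
        4: {"A": 0.55, "C": 0.12, "G": 0.13, "T": 0.20},
        5: {"A": 0.10, "C": 0.07, "G": 0.67, "T": 0.16},
        6: {"A": 0.20, "C": 0.10, "G": 0.12, "T": 0.58},
    }
    for pos in range(-up, 0):
        model.setdefault(pos, dict(exon_flat))
    for pos in range(1, down + 1):
        model.setdefault(pos, dict(flat))
    return {p: model[p] for p in sorted(model) if -up <= p <= down and p != 0}


def deplete_model(
    model: dict[int, dict[str, float]], position: int, nuc: str, factor: float
) -> dict[int, dict[str, float]]:
    """Return a copy with ``nuc`` at ``position`` depleted by ``factor``
    (probability divided by factor, remainder spread over the other bases)."""
    out = {p: dict(v) for p, v in model.items()}
    probs = out[position]
    removed = probs[nuc] * (1 - 1 / factor)
    probs[nuc] /= factor
    others = [n for n in NUCS if n != nuc and probs[n] > 0]
    for n in others:
        probs[n] += removed * probs[n] / sum(probs[m] for m in others)
    return out


@dataclass(frozen=True)
class InjectedEffect:
    gene_index: int
    kind: str  # DE | IR-gain | ES-change | alt-site-change
    magnitude: float  # log2 FC for DE, target log2 SIR otherwise


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic transcriptome.

    Defaults describe the desk-scale benchmark: 300 two-isoform-capable
    genes, 3 replicates each of wild type and mutant, common dispersion
    phi = 0.1, coverage set for ~50 reads per bin on average, and 30
    injected intron-retention gains at log2 SIR = 1.5.
    """

    n_genes: int = 300
    seed: int = 0
    genotypes: tuple[str, str] = ("wt", "mut")
    n_replicates: int = 3
    phi: float = 0.1
    mean_bin_reads: float = 50.0
    depth_sigma: float = 0.4  # lognormal spread of per-gene depth
    structure_mix: dict = field(
        default_factory=lambda: {"ES": 0.08, "IR": 0.08, "alt5": 0.08, "alt3": 0.08}
    )
    n_exons: tuple[int, int] = (3, 4)
    exon_length: tuple[int, int] = (100, 220)
    intron_length: tuple[int, int] = (100, 250)
    intergenic: int = 200
    baseline_retention: float = 0.15
    as_inclusion: float = 0.5  # wild-type share of the alternative isoform
    read_length: int = 100
    donor_model: dict[int, dict[str, float]] = field(default_factory=default_donor_model)
    effects: list[InjectedEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(self.structure_mix.values()) > 1 + 1e-9:
            raise ValueError("structure fractions must sum to <= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def default_effects(
    config: SimulationConfig,
    n_ir_gain: int = 30,
    ir_log2_sir: float = 1.5,
    n_de: int = 0,
    de_log2_fc: float = 2.0,
) -> list[InjectedEffect]:
    """Deterministically assign effects to distinct genes (IR gains go to
    genes without annotated AS structure so the injected event is a clean
    constitutive-intron bin)."""
    rng = np.random.default_rng(config.seed + 104729)
    kinds = _structure_assignment(config)
    plain = [i for i, k in enumerate(kinds) if k == "none"]
    if len(plain) < n_ir_gain + n_de:
        raise ValueError("not enough structureless genes for requested effects")
    chosen = rng.choice(len(plain), size=n_ir_gain + n_de, replace=False)
    effects = [
        InjectedEffect(plain[i], "IR-gain", ir_log2_sir) for i in chosen[:n_ir_gain]
    ]
    effects += [
        InjectedEffect(plain[i], "DE", de_log2_fc) for i in chosen[n_ir_gain:]
    ]
    return effects


def _structure_assignment(config: SimulationConfig) -> list[str]:
    """Deterministic gene -> AS structure map (cycled to match fractions)."""
    kinds: list[str] = []
    for struct, frac in sorted(config.structure_mix.items()):
        kinds += [struct] * int(round(frac * config.n_genes))
    kinds += ["none"] * (config.n_genes - len(kinds))
    return kinds[: config.n_genes]


# ---------------------------------------------------------------------------
# genome + annotation


@dataclass
class GeneStructure:
    """Generative description of one gene: isoforms, shares, retention."""

    gene: GeneModel
    structure: str  # none | ES | IR | alt5 | alt3
    depth: dict[str, float]  # genotype -> reads per exonic nt
    shares: dict[str, dict[str, float]]  # genotype -> {tx_id: share}
    retention: dict[str, dict[tuple[int, int], float]]  # genotype -> intron -> r
    canonical_introns: list[tuple[int, int]] = field(default_factory=list)


def _sample_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(NUCS))[rng.integers(0, 4, size=n)])


def _sample_from_model(
    rng: np.random.Generator, probs: dict[str, float]
) -> str:
    p = np.array([probs[n] for n in NUCS], dtype=float)
    return NUCS[rng.choice(4, p=p / p.sum())]


def sample_windows(
    model: dict[int, dict[str, float]],
    n: int,
    rng: np.random.Generator,
    site_type: str = "donor",
    up: int = 3,
    down: int = 10,
) -> SiteWindowSet:
    """Draw splice-site windows directly from a per-position model (used to
    test the site statistics without building a genome)."""
    positions = sorted(model)
    seqs = [
        "".join(_sample_from_model(rng, model[p]) for p in positions)
        for _ in range(n)
    ]
    return SiteWindowSet(site_type=site_type, up=up, down=down, sequences=seqs)


def _build_gene_sequence(
    rng: np.random.Generator,
    exon_lens: list[int],
    intron_lens: list[int],
    donor_model: dict[int, dict[str, float]],
) -> tuple[str, list[tuple[int, int]]]:
    """Transcript-orientation gene sequence and local exon intervals, with
    GT..AG introns whose donor windows follow the model."""
    up = -min(p for p in donor_model if p < 0)
    down = max(p for p in donor_model if p > 0)
    parts: list[str] = []
    exons_local: list[tuple[int, int]] = []
    pos = 0
    for i, elen in enumerate(exon_lens):
        exon = list(_sample_seq(rng, elen))
        if i < len(intron_lens):
            # last `up` exon bases come from the donor model's exonic side
            for j in range(min(up, elen)):
                exon[elen - up + j] = _sample_from_model(rng, donor_model[j - up])
        parts.append("".join(exon))
        exons_local.append((pos, pos + elen))
        pos += elen
        if i < len(intron_lens):
            ilen = intron_lens[i]
            intron = list(_sample_seq(rng, ilen))
            for j in range(min(down, ilen - 2)):
                intron[j] = _sample_from_model(rng, donor_model[j + 1])
            intron[0], intron[1] = "G", "T"
            intron[-2], intron[-1] = "A", "G"
            parts.append("".join(intron))
            pos += ilen
    return "".join(parts), exons_local


def _alt_isoform(
    structure: str,
    exons: list[tuple[int, int]],
    rng: np.random.Generator,
) -> list[tuple[int, int]] | None:
    """Second isoform realizing the requested AS structure (local coords)."""
    n = len(exons)
    if structure == "none" or n < 2:
        return None
    if structure == "ES" and n >= 3:
        skip = int(rng.integers(1, n - 1))
        return exons[:skip] + exons[skip + 1:]
    if structure == "IR":
        i = int(rng.integers(0, n - 1))
        merged = exons[:i] + [(exons[i][0], exons[i + 1][1])] + exons[i + 2:]
        return merged
    if structure in {"alt5", "alt3"}:
        i = int(rng.integers(0, n - 1))
        delta = int(rng.integers(20, 61))
        alt = list(exons)
        if structure == "alt5":  # donor moved upstream: exon i shortened at 3'
            s, e = alt[i]
            if e - s <= delta + 20:
                return None
            alt[i] = (s, e - delta)
        else:  # acceptor moved downstream: exon i+1 shortened at 5'
            s, e = alt[i + 1]
            if e - s <= delta + 20:
                return None
            alt[i + 1] = (s + delta, e)
        return alt
    return None


def generate_genome_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], list[GeneStructure]]:
    """Build the genome sequence, gene models and generative structures.

    Genes are laid out without overlap on one chromosome, alternating
    strand; minus-strand gene loci are reverse-complemented so splice
    motifs stay strand-correct.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    kinds = _structure_assignment(config)
    chrom = "chr1"
    seq_parts: list[str] = []
    offset = 0
    genes: list[GeneModel] = []
    structures: list[GeneStructure] = []
    for gi in range(config.n_genes):
        structure = kinds[gi]
        n_ex = int(rng.integers(config.n_exons[0], config.n_exons[1] + 1))
        exon_lens = [int(rng.integers(*config.exon_length)) for _ in range(n_ex)]
        intron_lens = [int(rng.integers(*config.intron_length)) for _ in range(n_ex - 1)]
        local_seq, exons_local = _build_gene_sequence(
            rng, exon_lens, intron_lens, config.donor_model
        )
        alt_local = _alt_isoform(structure, exons_local, rng)
        if alt_local is None:
            structure = "none"
        elif structure in {"alt5", "alt3"}:
            # the alternative isoform introduces a new splice site inside an
            # exon; plant the GT / AG motif so its intron is also GT..AG
            seq_list = list(local_seq)
            originals = set(exons_local)
            for s2, e2 in alt_local:
                if (s2, e2) in originals:
                    continue
                if any(s == s2 and e2 < e for s, e in originals):  # new donor
                    seq_list[e2], seq_list[e2 + 1] = "G", "T"
                if any(e == e2 and s2 > s for s, e in originals):  # new acceptor
                    seq_list[s2 - 2], seq_list[s2 - 1] = "A", "G"
            local_seq = "".join(seq_list)
        strand = "+" if gi % 2 == 0 else "-"
        L = len(local_seq)
        gene_id = f"G{gi:04d}"

        def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
            if strand == "+":
                return (offset + iv[0], offset + iv[1])
            return (offset + L - iv[1], offset + L - iv[0])

        tx = [(f"{gene_id}.1", tuple(sorted(to_genomic(iv) for iv in exons_local)))]
        if alt_local is not None:
            tx.append(
                (f"{gene_id}.2", tuple(sorted(to_genomic(iv) for iv in alt_local)))
            )
        span = (offset, offset + L)
        gene = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                         transcripts=tuple(tx), span=span)
        genes.append(gene)
        seq_parts.append(local_seq if strand == "+" else revcomp(local_seq))
        offset += L + config.intergenic
        seq_parts.append(_sample_seq(rng, config.intergenic))

        canonical = tx[0][1]
        introns = [(e1, s2) for (_, e1), (s2, _) in zip(canonical, canonical[1:])]
        genotypes = list(config.genotypes)
        psi = config.as_inclusion if alt_local is not None else 0.0
        shares = {
            g: ({tx[0][0]: 1 - psi, tx[1][0]: psi} if len(tx) == 2
                else {tx[0][0]: 1.0})
            for g in genotypes
        }
        retention = {
            g: {iv: config.baseline_retention for iv in introns} for g in genotypes
        }
        structures.append(
            GeneStructure(
                gene=gene, structure=structure,
                depth={g: 1.0 for g in genotypes},
                shares=shares, retention=retention,
                canonical_introns=introns,
            )
        )
    genome = {chrom: "".join(seq_parts)}
    return genome, genes, structures


# ---------------------------------------------------------------------------
# expected-count model and effect injection


def _bin_inclusion(b: Bin, struct: GeneStructure, genotype: str) -> float:
    """Fraction of the gene's transcript molecules from which reads over
    this bin originate (exonic share plus retained pre-mRNA share)."""
    incl = 0.0
    tx_by_id = dict(struct.gene.transcripts)
    for tx_id, share in struct.shares[genotype].items():
        exons = tx_by_id[tx_id]
        if b.end <= exons[0][0] or b.start >= exons[-1][1]:
            continue
        exonic = any(s <= b.start and b.end <= e for s, e in exons)
        if exonic:
            incl += share
        else:
            # intronic in this isoform: reads only from unspliced pre-mRNA
            for (e1, s2) in ((e1, s2) for (_, e1), (s2, _) in
                             zip(exons, exons[1:])):
                if e1 <= b.start and b.end <= s2:
                    r = struct.retention[genotype].get((e1, s2))
                    if r is None:  # non-canonical intron: use baseline of any
                        r = next(iter(struct.retention[genotype].values()), 0.0)
                    incl += share * r
                    break
    return incl


def _expected_bin_means(
    struct: GeneStructure, bins: list[Bin], genotype: str
) -> np.ndarray:
    d = struct.depth[genotype]
    return np.array(
        [d * b.length * _bin_inclusion(b, struct, genotype) for b in bins]
    )


def _expected_log2_sir(
    struct: GeneStructure, bins: list[Bin], b: Bin, exonic_len: float,
    genotypes: tuple[str, str],
) -> float:
    """Expected log2 SIR of one bin under the generative model (mutant over
    wild type), with gene density = expected gene total / exonic length."""
    wt, mut = genotypes
    out = {}
    for g in genotypes:
        means = _expected_bin_means(struct, bins, g)
        total = means.sum()
        if total <= 0 or exonic_len <= 0:
            return np.nan
        i = bins.index(b)
        out[g] = (means[i] / b.length) / (total / exonic_len)
    if out[wt] <= 0 or out[mut] <= 0:
        return np.nan
    return float(np.log2(out[mut] / out[wt]))


def apply_effects(
    structures: list[GeneStructure],
    binset: BinSet,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Inject the configured effects, solving retention / isoform-share
    shifts so the realized expected log2 SIR equals the target.

    Returns the ground-truth frame: one row per bin with the true expected
    log2 SIR and the injected-effect annotation.
    """
    wt, mut = config.genotypes
    exonic_len = gene_exonic_lengths(binset)
    rng = np.random.default_rng(config.seed + 7919)

    # per-gene depth: the analyzed bins (intron and AS) average
    # mean_bin_reads reads, lognormal spread across genes
    for struct in structures:
        bins = binset.gene_bins(struct.gene.gene_id)
        means = _expected_bin_means(struct, bins, wt)
        tested = [i for i, b in enumerate(bins) if b.kind != "exon"]
        if tested:
            base = means[tested].mean()
            scale = config.mean_bin_reads / base if base > 0 else 0.0
        else:
            base = means.mean()
            scale = config.mean_bin_reads / base if base > 0 else 0.0
        noise = float(np.exp(rng.normal(0, config.depth_sigma)
                             - config.depth_sigma ** 2 / 2))
        for g in config.genotypes:
            struct.depth[g] = scale * noise

    event_rows = []
    for eff in config.effects:
        struct = structures[eff.gene_index]
        gene_id = struct.gene.gene_id
        bins = binset.gene_bins(gene_id)
        if eff.kind == "DE":
            struct.depth[mut] *= 2.0 ** eff.magnitude
            event_rows.append((gene_id, None, "DE", eff.magnitude))
            continue
        if eff.kind == "IR-gain":
            if not struct.canonical_introns:
                raise ValueError(f"{gene_id}: no intron for IR-gain")
            intron = struct.canonical_introns[0]
            target_bin = next(
                b for b in bins
                if b.kind == "intron" and intron[0] <= b.start and b.end <= intron[1]
            )

            def gap(r: float) -> float:
                struct.retention[mut][intron] = r
                return (
                    _expected_log2_sir(struct, bins, target_bin,
                                       exonic_len[gene_id], config.genotypes)
                    - eff.magnitude
                )

            try:
                r_hat = brentq(gap, config.baseline_retention * 1.0001, 0.999)
            except ValueError as exc:
                raise ValueError(
                    f"target SIR {eff.magnitude} unreachable for {gene_id}"
                ) from exc
            struct.retention[mut][intron] = r_hat
            event_rows.append((gene_id, target_bin.bin_id, "IR-gain", eff.magnitude))
        elif eff.kind in {"ES-change", "alt-site-change"}:
            as_bins = [b for b in bins if b.kind == "AS"]
            if not as_bins:
                raise ValueError(f"{gene_id}: no AS bin for {eff.kind}")
            target_bin = as_bins[0]
            alt_id = struct.gene.transcripts[1][0]
            can_id = struct.gene.transcripts[0][0]

            def gap_psi(psi: float) -> float:
                struct.shares[mut] = {can_id: 1 - psi, alt_id: psi}
                return (
                    _expected_log2_sir(struct, bins, target_bin,
                                       exonic_len[gene_id], config.genotypes)
                    - eff.magnitude
                )

            try:
                psi_hat = brentq(gap_psi, 1e-4, 1 - 1e-4)
            except ValueError as exc:
                raise ValueError(
                    f"target SIR {eff.magnitude} unreachable for {gene_id}"
                ) from exc
            struct.shares[mut] = {can_id: 1 - psi_hat, alt_id: psi_hat}
            event_rows.append((gene_id, target_bin.bin_id, eff.kind, eff.magnitude))
        else:
            raise ValueError(f"unknown effect kind {eff.kind}")

    # ground truth: realized expected log2 SIR per intron/AS bin
    rows = []
    injected = {bid: (k, m) for _, bid, k, m in event_rows if bid is not None}
    de_genes = {g: m for g, _, k, m in event_rows if k == "DE"}
    for struct in structures:
        gene_id = struct.gene.gene_id
        bins = binset.gene_bins(gene_id)
        for b in bins:
            if b.kind == "exon":
                continue
            sir = _expected_log2_sir(struct, bins, b, exonic_len.get(gene_id, np.nan),
                                     config.genotypes)
            kind, mag = injected.get(b.bin_id, ("none", 0.0))
            rows.append((b.bin_id, gene_id, b.kind, b.event_class, sir,
                         kind, mag, de_genes.get(gene_id, 0.0)))
    return pd.DataFrame(
        rows,
        columns=["bin_id", "gene_id", "kind", "event_class", "true_log2_sir",
                 "injected", "target_log2_sir", "gene_log2_fc"],
    ).set_index("bin_id")


# ---------------------------------------------------------------------------
# count simulation


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def make_design(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        (f"{g}_{rep + 1}", g, str(rep + 1))
        for g in config.genotypes
        for rep in range(config.n_replicates)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "replicate"])


def simulate_counts(
    binset: BinSet,
    structures: list[GeneStructure],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountTable, CountTable]:
    """NB gene totals split multinomially across bins (dispersion-preserving).

    Gene counts are the sampled totals; bin counts sum to them exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    design = make_design(config)
    bin_ids = [b.bin_id for b in binset.bins]
    bin_pos = {bid: i for i, bid in enumerate(bin_ids)}
    gene_ids = [s.gene.gene_id for s in structures]
    n_s = len(design)
    bin_counts = np.zeros((len(bin_ids), n_s), dtype=np.int64)
    gene_counts = np.zeros((len(gene_ids), n_s), dtype=np.int64)

    for gi, struct in enumerate(structures):
        bins = binset.gene_bins(struct.gene.gene_id)
        idx = [bin_pos[b.bin_id] for b in bins]
        means = {g: _expected_bin_means(struct, bins, g) for g in config.genotypes}
        for sj, row in design.iterrows():
            mu = means[row["genotype"]]
            total_mu = mu.sum()
            if total_mu <= 0:
                continue
            total = int(_nb_sample(rng, np.array([total_mu]), config.phi)[0])
            gene_counts[gi, sj] = total
            if total > 0:
                split = rng.multinomial(total, mu / total_mu)
                bin_counts[idx, sj] += split

    lib = pd.Series(gene_counts.sum(axis=0), index=design["sample_id"], dtype=float)
    lib[lib == 0] = 1.0  # degenerate zero-depth guard
    bin_table = CountTable(
        counts=pd.DataFrame(bin_counts, index=bin_ids,
                            columns=list(design["sample_id"])),
        design=design,
        feature_lengths=pd.Series({b.bin_id: float(b.length) for b in binset.bins}),
        library_sizes=lib,
    )
    exonic = gene_exonic_lengths(binset)
    gene_table = CountTable(
        counts=pd.DataFrame(gene_counts, index=gene_ids,
                            columns=list(design["sample_id"])),
        design=design,
        feature_lengths=exonic.reindex(gene_ids).fillna(1.0),
        library_sizes=lib,
    )
    return bin_table, gene_table


# ---------------------------------------------------------------------------
# read simulation


def _transcript_variants(struct: GeneStructure, genotype: str):
    """(exon_chain, expected-share) sources: annotated isoforms plus, for
    each canonical intron, a single-intron-retained pre-mRNA variant."""
    tx_by_id = dict(struct.gene.transcripts)
    can_id = struct.gene.transcripts[0][0]
    out = []
    retention = struct.retention[genotype]
    r_total = sum(retention.values())
    for tx_id, share in struct.shares[genotype].items():
        if tx_id == can_id:
            spliced_share = share * max(1 - r_total, 0.0)
            out.append((list(tx_by_id[tx_id]), spliced_share))
            for (e1, s2), r in retention.items():
                exons = list(tx_by_id[tx_id])
                merged = []
                for ex in exons:
                    if merged and merged[-1][1] == e1 and ex[0] == s2:
                        merged[-1] = (merged[-1][0], ex[1])
                    else:
                        merged.append(ex)
                out.append((merged, share * r))
        else:
            out.append((list(tx_by_id[tx_id]), share))
    return [(chain, s) for chain, s in out if s > 0]


def simulate_reads(
    genome: dict[str, str],
    structures: list[GeneStructure],
    binset: BinSet,
    config: SimulationConfig,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Emit sorted, indexed BAMs (one per sample) with gapped CIGARs, plus
    the ground-truth per-bin overlap tallies of the emitted reads.

    Reads start uniformly along each source transcript; skipped introns
    become N operations.  Returns (sample -> BAM path, tally frame with
    bins x samples counts).
    """
    import pysam

    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = make_design(config)
    rl = config.read_length
    chrom = next(iter(genome))
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": len(genome[chrom])}]}

    from intervaltree import IntervalTree

    tree = IntervalTree()
    for i, b in enumerate(binset.bins):
        tree.addi(b.start, b.end, i)
    bin_ids = [b.bin_id for b in binset.bins]
    tallies = np.zeros((len(bin_ids), len(design)), dtype=np.int64)
    paths: dict[str, Path] = {}

    for sj, row in design.iterrows():
        sample = row["sample_id"]
        genotype = row["genotype"]
        reads = []  # (pos, cigar list, seq)
        for struct in structures:
            d = struct.depth[genotype]
            for chain, share in _transcript_variants(struct, genotype):
                tx_len = sum(e - s for s, e in chain)
                n_starts = tx_len - rl + 1
                if n_starts <= 0:
                    logger.warning("transcript of %s shorter than read; skipped",
                                   struct.gene.gene_id)
                    continue
                n_reads = int(rng.poisson(d * share * n_starts))
                starts = rng.integers(0, n_starts, size=n_reads)
                for st in starts:
                    blocks = _tx_to_blocks(chain, int(st), rl)
                    reads.append(blocks)
                    hit = set()
                    for bs, be in blocks:
                        for iv in tree.overlap(bs, be):
                            hit.add(iv.data)
                    for bi in hit:
                        tallies[bi, sj] += 1
        reads.sort(key=lambda blocks: blocks[0][0])
        path = out_dir / f"{sample}.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for ri, blocks in enumerate(reads):
                a = pysam.AlignedSegment()
                a.query_name = f"{sample}_r{ri}"
                a.reference_id = 0
                a.reference_start = blocks[0][0]
                a.mapping_quality = 60
                cigar = []
                for k, (bs, be) in enumerate(blocks):
                    if k > 0:
                        cigar.append((3, bs - blocks[k - 1][1]))  # N
                    cigar.append((0, be - bs))  # M
                a.cigartuples = cigar
                a.query_sequence = "".join(
                    genome[chrom][bs:be] for bs, be in blocks
                )
                a.flag = 0
                bam.write(a)
        pysam.index(str(path))
        paths[sample] = path

    tally_frame = pd.DataFrame(tallies, index=bin_ids,
                               columns=list(design["sample_id"]))
    return paths, tally_frame


def _tx_to_blocks(chain, start: int, length: int) -> list[tuple[int, int]]:
    """Map a transcript-coordinate read to genomic (start, end) blocks."""
    blocks = []
    remaining = length
    offset = start
    for s, e in chain:
        ex_len = e - s
        if offset >= ex_len:
            offset -= ex_len
            continue
        take = min(remaining, ex_len - offset)
        blocks.append((s + offset, s + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    return blocks


# ---------------------------------------------------------------------------
# file emission


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Minimal GFF3 (gene/mRNA/exon), 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tbinsplice\tgene\t{g.span[0] + 1}\t{g.span[1]}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for tx_id, exons in g.transcripts:
                fh.write(
                    f"{g.chrom}\tbinsplice\tmRNA\t{exons[0][0] + 1}\t{exons[-1][1]}"
                    f"\t.\t{g.strand}\t.\tID={tx_id};Parent={g.gene_id}\n"
                )
                for s, e in exons:
                    fh.write(
                        f"{g.chrom}\tbinsplice\texon\t{s + 1}\t{e}\t.\t{g.strand}"
                        f"\t.\tParent={tx_id}\n"
                    )


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    structures: list[GeneStructure]
    binset: BinSet
    truth: pd.DataFrame
    bin_table: CountTable
    gene_table: CountTable

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "annotation": out / "annotation.gff3",
            "design": out / "design.tsv",
            "truth": out / "truth.tsv",
            "bin_counts": out / "bin_counts.tsv",
            "gene_counts": out / "gene_counts.tsv",
            "library_sizes": out / "library_sizes.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_gff3(self.genes, paths["annotation"])
        make_design(self.config).to_csv(paths["design"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t")
        self.bin_table.to_tsv(paths["bin_counts"])
        self.gene_table.to_tsv(paths["gene_counts"])
        self.bin_table.library_sizes.rename("library_size").to_csv(
            paths["library_sizes"], sep="\t", index_label="sample_id"
        )
        return paths


def simulate_dataset(
    config: SimulationConfig | None = None,
    n_ir_gain: int = 30,
    ir_log2_sir: float = 1.5,
    n_de: int = 0,
    de_log2_fc: float = 2.0,
    seed: int | None = None,
) -> SyntheticDataset:
    """One-call benchmark dataset: genome, annotation, bins, ground truth
    and count tables under the default study conditions."""
    if config is None:
        config = SimulationConfig(seed=0 if seed is None else seed)
    elif seed is not None:
        config.seed = seed
    genome, genes, structures = generate_genome_annotation(config)
    binset = partition_transcriptome(genes)
    if not config.effects:
        config.effects = default_effects(
            config, n_ir_gain=n_ir_gain, ir_log2_sir=ir_log2_sir,
            n_de=n_de, de_log2_fc=de_log2_fc,
        )
    truth = apply_effects(structures, binset, config)
    bin_table, gene_table = simulate_counts(binset, structures, config)
    return SyntheticDataset(
        config=config, genome=genome, genes=genes, structures=structures,
        binset=binset, truth=truth, bin_table=bin_table, gene_table=gene_table,
    )
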