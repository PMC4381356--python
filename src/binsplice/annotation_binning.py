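"""Flatten multi-isoform gene models into disjoint exon/intron/AS bins.

Each gene span is cut at every distinct exon boundary across all of its
transcripts.  A resulting interval ("bin") is exonic or intronic uniformly
within every transcript that spans it; bins exonic in all spanning
transcripts are exon-bins, intronic in all are intron-bins, and mixed bins
are AS-bins carrying an event class (ES, alt5, alt3, IR, multiple).

All internal coordinates are 0-based half-open; GFF3/GTF 1-based inclusive
coordinates are converted at the file boundary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

EVENT_CLASSES = ("ES", "alt5", "alt3", "IR", "multiple", "none")


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts, each an ordered list of exons.

    Exons are 0-based half-open ``(start, end)`` tuples, non-overlapping and
    sorted within a transcript.  ``span`` is the union extent over all
    transcripts.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for tx_id, exons in self.transcripts:
            if not exons:
                raise ValueError(f"transcript {tx_id} has no exons")
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if not (s1 < e1 <= s2 < e2):
                    raise ValueError(f"exons of {tx_id} unsorted or overlapping")
            if exons[0][0] < self.span[0] or exons[-1][1] > self.span[1]:
                raise ValueError(f"exon of {tx_id} outside gene span")

    def transcript_span(self, exons: Sequence[tuple[int, int]]) -> tuple[int, int]:
        return exons[0][0], exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Distinct introns (gaps between consecutive exons) over all transcripts."""
        out = set()
        for _, exons in self.transcripts:
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                out.add((e1, s2))
        return sorted(out)


@dataclass(frozen=True)
class Bin:
    """A subgenic interval with uniform exon/intron status per transcript."""

    bin_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    kind: str  # exon | intron | AS
    event_class: str  # ES | alt5 | alt3 | IR | multiple | none
    ambiguous: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty bin {self.bin_id}")
        if (self.kind == "AS") != (self.event_class != "none"):
            raise ValueError(f"kind/event_class mismatch in {self.bin_id}")


@dataclass
class BinSet:
    """All bins of a partitioned transcriptome plus summary bookkeeping."""

    bins: list[Bin]
    monoexonic_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._by_gene: dict[str, list[Bin]] = {}
        for b in self.bins:
            self._by_gene.setdefault(b.gene_id, []).append(b)

    def gene_bins(self, gene_id: str) -> list[Bin]:
        return self._by_gene.get(gene_id, [])

    @property
    def gene_ids(self) -> list[str]:
        return list(self._by_gene)

    def summary(self) -> dict[str, int]:
        kinds = Counter(b.kind for b in self.bins)
        classes = Counter(b.event_class for b in self.bins if b.kind == "AS")
        out = {
            "total": len(self.bins),
            "exon": kinds.get("exon", 0),
            "intron": kinds.get("intron", 0),
            "AS": kinds.get("AS", 0),
            "ambiguous": sum(b.ambiguous for b in self.bins),
            "monoexonic_genes": len(self.monoexonic_genes),
        }
        for cls in ("ES", "alt5", "alt3", "IR", "multiple"):
            out[f"AS_{cls}"] = classes.get(cls, 0)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (b.bin_id, b.gene_id, b.chrom, b.start, b.end, b.strand, b.kind,
             b.event_class, b.length, b.ambiguous)
            for b in self.bins
        ]
        return pd.DataFrame(
            rows,
            columns=["bin_id", "gene_id", "chrom", "start", "end", "strand",
                     "kind", "event_class", "length", "ambiguous"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for b in self.bins:
                fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.bin_id}\t0\t{b.strand}\n")


def _status_in_transcript(pos_interval: tuple[int, int],
                          exons: Sequence[tuple[int, int]]) -> str | None:
    """Status of an interval within one transcript: 'exon', 'intron' or None.

    The interval must not straddle an exon boundary of this transcript
    (guaranteed when it comes from the boundary cut).
    """
    start, end = pos_interval
    tx_start, tx_end = exons[0][0], exons[-1][1]
    if end <= tx_start or start >= tx_end:
        return None
    for s, e in exons:
        if s <= start and end <= e:
            return "exon"
    return "intron"


def _base_status(pos: int, exons: Sequence[tuple[int, int]]) -> str | None:
    tx_start, tx_end = exons[0][0], exons[-1][1]
    if pos < tx_start or pos >= tx_end:
        return None
    for s, e in exons:
        if s <= pos < e:
            return "exon"
    return "intron"


def classify_event(
    bin_interval: tuple[int, int],
    intronic_transcripts: Iterable[Sequence[tuple[int, int]]],
    strand: str,
) -> str:
    """Classify an AS bin from the flanking-base status in each transcript
    where the bin is intronic.

    Flank rule per intronic transcript, looking at the bases immediately
    left and right of the bin: (intron, intron) -> ES (the bin's exon is
    skipped); (exon, exon) -> IR (the bin is a retained intron in the other
    isoforms); (exon, intron) -> alternative donor on '+' (alt5), acceptor on
    '-'; (intron, exon) -> the mirror.  Conflicting votes across transcripts,
    or a flank outside the transcript span, yield 'multiple'.
    """
    start, end = bin_interval
    votes = set()
    for exons in intronic_transcripts:
        left = _base_status(start - 1, exons)
        right = _base_status(end, exons)
        if left is None or right is None:
            return "multiple"
        if (left, right) == ("intron", "intron"):
            votes.add("ES")
        elif (left, right) == ("exon", "exon"):
            votes.add("IR")
        elif (left, right) == ("exon", "intron"):
            votes.add("alt5" if strand == "+" else "alt3")
        else:  # (intron, exon)
            votes.add("alt3" if strand == "+" else "alt5")
    if not votes:
        raise ValueError("classify_event needs at least one intronic transcript")
    if len(votes) > 1:
        return "multiple"
    return votes.pop()


def flatten_gene(gene: GeneModel) -> list[Bin]:
    """Cut the gene span at every exon boundary and classify each piece.

    Only transcripts overlapping a piece vote on its status; a piece exonic
    in all voters is an exon-bin, intronic in all an intron-bin, mixed an
    AS-bin classified by :func:`classify_event`.
    """
    boundaries = {gene.span[0], gene.span[1]}
    for _, exons in gene.transcripts:
        for s, e in exons:
            boundaries.add(s)
            boundaries.add(e)
    cuts = sorted(boundaries)
    bins: list[Bin] = []
    idx = 0
    for start, end in zip(cuts, cuts[1:]):
        statuses = []
        intronic_tx = []
        for _, exons in gene.transcripts:
            st = _status_in_transcript((start, end), exons)
            if st is None:
                continue
            statuses.append(st)
            if st == "intron":
                intronic_tx.append(exons)
        if not statuses:
            # span gap not covered by any transcript (possible with disjoint
            # transcript spans); treat as intronic for the gene
            kind, event = "intron", "none"
        elif all(s == "exon" for s in statuses):
            kind, event = "exon", "none"
        elif all(s == "intron" for s in statuses):
            kind, event = "intron", "none"
        else:
            kind = "AS"
            event = classify_event((start, end), intronic_tx, gene.strand)
        idx += 1
        bins.append(
            Bin(
                bin_id=f"{gene.gene_id}:{idx:03d}",
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                start=start,
                end=end,
                kind=kind,
                event_class=event,
            )
        )
    return bins


def is_monoexonic(gene: GeneModel) -> bool:
    return all(len(exons) == 1 for _, exons in gene.transcripts)


def partition_transcriptome(genes: Iterable[GeneModel]) -> BinSet:
    """Flatten every gene and flag bins overlapping another gene as ambiguous.

    Ambiguity is strand-blind (counting is unstranded downstream); ambiguous
    bins are kept in the table but excluded from read counting by default.
    """
    genes = list(genes)
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.span[0], g.span[1], g.gene_id)

    all_bins: list[Bin] = []
    mono: set[str] = set()
    for g in genes:
        if is_monoexonic(g):
            mono.add(g.gene_id)
        tree = trees[g.chrom]
        for b in flatten_gene(g):
            hits = tree.overlap(b.start, b.end)
            ambiguous = any(iv.data != g.gene_id for iv in hits)
            if ambiguous:
                b = Bin(b.bin_id, b.gene_id, b.chrom, b.strand, b.start, b.end,
                        b.kind, b.event_class, ambiguous=True)
            all_bins.append(b)
    return BinSet(all_bins, monoexonic_genes=mono)


# ---------------------------------------------------------------------------
# annotation reading


def _detect_dialect(path: str | Path) -> str:
    name = str(path).lower()
    if name.endswith((".gtf", ".gtf.gz")):
        return "gtf"
    return "gff3"


def load_annotation(path: str | Path) -> list[GeneModel]:
    """Read a GFF3 or GTF annotation into GeneModels.

    File coordinates (1-based inclusive) are converted to 0-based half-open.
    Transcripts without exons are skipped with a warning.  Genes are returned
    sorted by (chrom, span start, gene_id) for deterministic downstream
    output.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _detect_dialect(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=(dialect == "gff3"),
            disable_infer_transcripts=(dialect == "gff3"),
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ValueError(f"could not parse annotation {path}: {exc}") from exc

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        children = list(db.children(gene, level=1))
        tx_feats = [c for c in children
                    if c.featuretype in {"mRNA", "transcript", "ncRNA", "tRNA", "rRNA"}]
        for tx in tx_feats:
            exons = sorted(
                (e.start - 1, e.end)
                for e in db.children(tx, featuretype="exon")
            )
            if not exons:
                logger.warning("transcript %s has no exons; skipped", tx.id)
                continue
            transcripts.append((tx.id, tuple(exons)))
        if not transcripts:
            logger.warning("gene %s has no usable transcripts; skipped", gene.id)
            continue
        span = (min(e[0][0] for _, e in transcripts),
                max(e[-1][1] for _, e in transcripts))
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                transcripts=tuple(transcripts),
                span=span,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes
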