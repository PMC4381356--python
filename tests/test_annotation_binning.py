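"""Bin flattening, event classification and the per-base partition oracle."""

from __future__ import annotations

import numpy as np
import pytest

from binsplice.annotation_binning import (
    GeneModel,
    classify_event,
    flatten_gene,
    load_annotation,
    partition_transcriptome,
)
from binsplice.synthetic_data import write_gff3

from conftest import base_status_oracle, random_gene


def as_tuples(bins):
    return [(b.start, b.end, b.kind, b.event_class) for b in bins]


def test_alt3_worked_gene(gene_alt3):
    assert as_tuples(flatten_gene(gene_alt3)) == [
        (0, 100, "exon", "none"),
        (100, 150, "intron", "none"),
        (150, 200, "AS", "alt3"),
        (200, 300, "exon", "none"),
    ]


def test_exon_skipping_worked_gene(gene_es):
    assert as_tuples(flatten_gene(gene_es)) == [
        (0, 100, "exon", "none"),
        (100, 200, "intron", "none"),
        (200, 250, "AS", "ES"),
        (250, 300, "intron", "none"),
        (300, 400, "exon", "none"),
    ]


def test_single_isoform_has_no_as_bins():
    g = GeneModel("g", "chr1", "+", (("g.1", ((0, 100), (200, 300))),), (0, 300))
    assert as_tuples(flatten_gene(g)) == [
        (0, 100, "exon", "none"),
        (100, 200, "intron", "none"),
        (200, 300, "exon", "none"),
    ]


def test_monoexonic_gene_single_bin():
    g = GeneModel("g", "chr1", "+", (("g.1", ((0, 150),)),), (0, 150))
    assert as_tuples(flatten_gene(g)) == [(0, 150, "exon", "none")]


@pytest.mark.parametrize(
    "interval,intronic_exons,strand,expected",
    [
        # intronic isoform has intron [100,200): flanks (intron, exon)
        ((150, 200), ((0, 100), (200, 300)), "+", "alt3"),
        ((150, 200), ((0, 100), (200, 300)), "-", "alt5"),
        # bin inside intron [100,300) of skipping isoform
        ((200, 250), ((0, 100), (300, 400)), "+", "ES"),
        # bin equals intron [100,200) of spliced isoform: flanks (exon, exon)
        ((100, 200), ((0, 100), (200, 300)), "+", "IR"),
        # flanks (exon, intron)
        ((100, 150), ((0, 100), (200, 300)), "+", "alt5"),
        ((100, 150), ((0, 100), (200, 300)), "-", "alt3"),
    ],
)
def test_classify_event_rule_table(interval, intronic_exons, strand, expected):
    assert classify_event(interval, [intronic_exons], strand) == expected


def test_classify_event_conflicting_votes_is_multiple():
    # one isoform sees (intron,intron), another (exon,exon)
    cls = classify_event(
        (100, 200),
        [((0, 100), (200, 300)), ((0, 50), (250, 300))],
        "+",
    )
    assert cls == "multiple"


def test_classify_event_flank_outside_span_is_multiple():
    assert classify_event((100, 200), [((100, 150), (180, 250))], "+") == "multiple"


def test_classify_event_requires_intronic_transcript():
    with pytest.raises(ValueError):
        classify_event((0, 10), [], "+")


def test_partition_totals_for_worked_genes(gene_alt3, gene_es):
    # shift the second gene away so the two genes do not overlap
    shifted = GeneModel(
        gene_es.gene_id, gene_es.chrom, gene_es.strand,
        tuple((tid, tuple((s + 1000, e + 1000) for s, e in ex))
              for tid, ex in gene_es.transcripts),
        (gene_es.span[0] + 1000, gene_es.span[1] + 1000),
    )
    summary = partition_transcriptome([gene_alt3, shifted]).summary()
    assert summary["exon"] == 4
    assert summary["intron"] == 3
    assert summary["AS"] == 2
    assert summary["AS_alt3"] == 1 and summary["AS_ES"] == 1


def test_overlapping_genes_flagged_ambiguous(gene_alt3):
    other = GeneModel(
        "gC", "chr1", "-", (("gC.1", ((250, 500),)),), (250, 500)
    )
    binset = partition_transcriptome([gene_alt3, other])
    flagged = {b.bin_id for b in binset.bins if b.ambiguous}
    # the shared 50 nt touch gA's last exon bin and gC's single bin
    assert any(b.startswith("gA") for b in flagged)
    assert any(b.startswith("gC") for b in flagged)
    untouched = [b for b in binset.bins if b.end <= 250]
    assert not any(b.ambiguous for b in untouched)


def test_duplicate_gene_id_rejected(gene_alt3):
    with pytest.raises(ValueError, match="duplicate"):
        partition_transcriptome([gene_alt3, gene_alt3])


def test_partition_matches_per_base_oracle_and_tiles():
    """Bins tile each gene span exactly and agree with brute-force per-base
    exon/intron status in every overlapping transcript (200 random genes;
    the full 1,000-gene sweep runs in the acceptance suite)."""
    rng = np.random.default_rng(42)
    for gi in range(200):
        gene = random_gene(rng, f"g{gi}")
        bins = flatten_gene(gene)
        # tiling
        assert bins[0].start == gene.span[0] and bins[-1].end == gene.span[1]
        for a, b in zip(bins, bins[1:]):
            assert a.end == b.start
        assert sum(b.length for b in bins) == gene.span[1] - gene.span[0]
        # per-base oracle
        for b in bins:
            for pos in range(b.start, b.end):
                statuses = {
                    st
                    for _, exons in gene.transcripts
                    if (st := base_status_oracle(pos, exons)) is not None
                }
                if not statuses:
                    expected = "intron"
                elif statuses == {"exon"}:
                    expected = "exon"
                elif statuses == {"intron"}:
                    expected = "intron"
                else:
                    expected = "AS"
                assert b.kind == expected, (gene.gene_id, b)


def test_gff3_roundtrip_and_coordinate_convention(tmp_path, gene_alt3, gene_es):
    path = tmp_path / "two_genes.gff3"
    shifted = GeneModel(
        gene_es.gene_id, gene_es.chrom, gene_es.strand,
        tuple((tid, tuple((s + 1000, e + 1000) for s, e in ex))
              for tid, ex in gene_es.transcripts),
        (1000, 1400),
    )
    write_gff3([gene_alt3, shifted], path)
    loaded = load_annotation(path)
    assert [g.gene_id for g in loaded] == ["gA", "gB"]
    # a GFF3 exon written 1..100 comes back as [0, 100)
    assert loaded[0].transcripts[0][1][0] == (0, 100)
    assert loaded[0].span == (0, 300)
    # loading is deterministic and byte-stable
    frame1 = partition_transcriptome(loaded).to_frame()
    frame2 = partition_transcriptome(load_annotation(path)).to_frame()
    assert frame1.equals(frame2)


def test_load_gtf_dialect(tmp_path):
    gtf = tmp_path / "mini.gtf"
    lines = [
        'chr1\tsrc\tgene\t1\t300\t.\t+\t.\tgene_id "gA";',
        'chr1\tsrc\ttranscript\t1\t300\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";',
        'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";',
        'chr1\tsrc\texon\t201\t300\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";',
    ]
    gtf.write_text("\n".join(lines) + "\n")
    genes = load_annotation(gtf)
    assert len(genes) == 1
    assert genes[0].transcripts[0][1] == ((0, 100), (200, 300))


def test_missing_file_raises():
    with pytest.raises(FileNotFoundError):
        load_annotation("/nonexistent/annotation.gff3")
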