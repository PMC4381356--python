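"""Shared fixtures: hand-built gene models, random-gene builder, and a small
synthetic dataset reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from binsplice.annotation_binning import GeneModel


@pytest.fixture
def gene_alt3() -> GeneModel:
    """Two isoforms sharing a donor but using alternative acceptors:
    A: exons [0,100)+[200,300); B: exons [0,100)+[150,300)."""
    return GeneModel(
        gene_id="gA",
        chrom="chr1",
        strand="+",
        transcripts=(
            ("gA.1", ((0, 100), (200, 300))),
            ("gA.2", ((0, 100), (150, 300))),
        ),
        span=(0, 300),
    )


@pytest.fixture
def gene_es() -> GeneModel:
    """Middle exon skipped by the second isoform:
    A: [0,100)+[200,250)+[300,400); B: [0,100)+[300,400)."""
    return GeneModel(
        gene_id="gB",
        chrom="chr1",
        strand="+",
        transcripts=(
            ("gB.1", ((0, 100), (200, 250), (300, 400))),
            ("gB.2", ((0, 100), (300, 400))),
        ),
        span=(0, 400),
    )


def random_gene(rng: np.random.Generator, gene_id: str, offset: int = 0) -> GeneModel:
    """A random multi-isoform gene for oracle-based partition tests.

    Exons are drawn on a base grid and each of 1-3 isoforms keeps a random
    non-empty subset of internal exons (first/last always kept), possibly
    with shifted internal boundaries, so ES/IR/alt-site topologies all
    arise.
    """
    n_ex = int(rng.integers(2, 6))
    pos = offset
    exons = []
    for _ in range(n_ex):
        pos += int(rng.integers(20, 120))  # intron (ignored before first exon)
        start = pos
        pos += int(rng.integers(30, 150))
        exons.append((start, pos))
    transcripts = []
    n_tx = int(rng.integers(1, 4))
    for t in range(n_tx):
        keep = [exons[0]]
        for ex in exons[1:-1]:
            if rng.random() < 0.75:
                s, e = ex
                if rng.random() < 0.3 and e - s > 40:  # alt boundary
                    if rng.random() < 0.5:
                        s += int(rng.integers(10, (e - s) // 2))
                    else:
                        e -= int(rng.integers(10, (e - s) // 2))
                keep.append((s, e))
        if n_ex > 1:
            keep.append(exons[-1])
        merged = []
        for s, e in sorted(keep):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
            else:
                merged.append((s, e))
        transcripts.append((f"{gene_id}.{t + 1}", tuple(merged)))
    # dedupe identical isoforms
    transcripts = list(dict((tuple(ex), (tid, ex)) for tid, ex in transcripts).values())
    span = (
        min(ex[0][0] for _, ex in transcripts),
        max(ex[-1][1] for _, ex in transcripts),
    )
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id=gene_id, chrom="chr1", strand=strand,
                     transcripts=tuple(transcripts), span=span)


def base_status_oracle(pos: int, exons) -> str | None:
    """Brute-force exon/intron status of one base in one transcript."""
    if pos < exons[0][0] or pos >= exons[-1][1]:
        return None
    return "exon" if any(s <= pos < e for s, e in exons) else "intron"


@pytest.fixture(scope="session")
def small_dataset():
    """A small benchmark dataset (60 genes, 6 injected IR gains) shared by
    the pipeline-level tests."""
    from binsplice.synthetic_data import SimulationConfig, simulate_dataset

    config = SimulationConfig(n_genes=60, seed=11)
    return simulate_dataset(config, n_ir_gain=6, n_de=4)
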