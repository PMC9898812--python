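"""Shared fixtures: a hand-built mini genome and a generated toy dataset."""

from __future__ import annotations

import pytest

from regbash.annotation import FeatureInterval, GenomeAnnotation, Transcript, revcomp
from regbash.consequence import classify_alleles
from regbash.synthetic_data import (
    SyntheticConfig,
    generate_alleles,
    generate_toy_genome,
)
from regbash.variants import Allele


def _iv(chrom, start, end, strand, kind, tid, gid):
    return FeatureInterval(chrom, start, end, strand, kind, tid, gid)


@pytest.fixture(scope="session")
def mini_genome() -> GenomeAnnotation:
    """Three hand-placed plus-strand genes on one 200-bp chromosome.

    gA: single exon (5,33), CDS (10,28) = ATG AAA CTT TAC TGG TAA
    gB: two exons (50,70)+(80,100), CDS (55,70)+(80,95), intron GT..AG
    gC: single exon (110,138), CDS (115,133) = ATG GGA TTT GCA CAT TAA
        (the GGA|TTT junction allows a synonymous change creating a GT)
    """
    seq = ["C"] * 200
    def put(pos, s):
        seq[pos : pos + len(s)] = list(s)

    put(10, "ATGAAACTTTACTGGTAA")
    put(55, "ATGGCAGCAGCAGCA")
    put(70, "GTCCCCCCAG")
    put(80, "GCAGCAGCAGCTTAA")
    put(115, "ATGGGATTTGCACATTAA")
    chrom = "chrT"
    sequences = {chrom: "".join(seq)}

    tA = Transcript(
        "tA.1", "gA", chrom, "+",
        exons=[_iv(chrom, 5, 33, "+", "exon", "tA.1", "gA")],
        cds=[_iv(chrom, 10, 28, "+", "CDS", "tA.1", "gA")],
    )
    tB = Transcript(
        "tB.1", "gB", chrom, "+",
        exons=[_iv(chrom, 50, 70, "+", "exon", "tB.1", "gB"),
               _iv(chrom, 80, 100, "+", "exon", "tB.1", "gB")],
        cds=[_iv(chrom, 55, 70, "+", "CDS", "tB.1", "gB"),
             _iv(chrom, 80, 95, "+", "CDS", "tB.1", "gB")],
    )
    tC = Transcript(
        "tC.1", "gC", chrom, "+",
        exons=[_iv(chrom, 110, 138, "+", "exon", "tC.1", "gC")],
        cds=[_iv(chrom, 115, 133, "+", "CDS", "tC.1", "gC")],
    )
    return GenomeAnnotation(sequences, [tA, tB, tC], flank_bp=5)


@pytest.fixture(scope="session")
def toy_dataset():
    """Generated genome + 1000 construction-forced alleles + calls."""
    cfg = SyntheticConfig(seed=7, n_alleles=1000)
    sequences, ann = generate_toy_genome(cfg)
    alleles, gt = generate_alleles(ann, cfg)
    calls = classify_alleles(alleles, ann)
    return {"config": cfg, "sequences": sequences, "annotation": ann,
            "alleles": alleles, "ground_truth": gt, "calls": calls}


def mirror_dataset(sequences, annotation, alleles):
    """Reverse-complement every chromosome and mirror all coordinates."""
    lengths = {c: len(s) for c, s in sequences.items()}
    mirrored_seqs = {c: revcomp(s) for c, s in sequences.items()}
    new_txs = []
    for tx in annotation.transcripts.values():
        L = lengths[tx.chrom]
        strand = "-" if tx.strand == "+" else "+"
        ex = [FeatureInterval(tx.chrom, L - e.end, L - e.start, strand, "exon",
                              tx.id, tx.gene_id) for e in tx.exons]
        cd = [FeatureInterval(tx.chrom, L - c.end, L - c.start, strand, "CDS",
                              tx.id, tx.gene_id) for c in tx.cds]
        new_txs.append(Transcript(tx.id, tx.gene_id, tx.chrom, strand, ex, cd))
    mirrored_ann = GenomeAnnotation(mirrored_seqs, new_txs, flank_bp=annotation.flank_bp)
    mirrored_alleles = [
        Allele(id=a.id, chrom=a.chrom, pos=lengths[a.chrom] - a.pos - len(a.ref),
               ref=revcomp(a.ref), alt=revcomp(a.alt), source=a.source)
        for a in alleles
    ]
    return mirrored_seqs, mirrored_ann, mirrored_alleles
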