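"""Transcript-centric genome annotation model.

Reads GFF3 + FASTA into genes -> transcripts -> exon/CDS intervals, derives
the features that matter for allele classification (UTRs, introns, 2-bp
splice sites, upstream/downstream flanks), and resolves overlapping features
conservatively so that every base carries a single, highest-precedence label.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open.  GFF3 I/O is 1-based, closed;
BED output is 0-based, half-open.  A minus-strand transcript stores its exons
in transcript order (5' to 3', i.e. descending genomic start); use
:attr:`Transcript.exons_genomic` for the genomically sorted view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "AnnotationError",
    "FeatureInterval",
    "Transcript",
    "GenomeAnnotation",
    "read_gff3",
    "write_gff3",
    "derive_transcript_features",
    "resolve_overlaps",
    "write_feature_bed",
    "DEFAULT_PRECEDENCE",
    "DEFAULT_FLANK_BP",
    "FEATURE_KINDS",
]

# Flank extent default: regulatory elements are overwhelmingly found within
# 5 kb of the TSS, so classification beyond that falls back to "intergenic".
DEFAULT_FLANK_BP = 5000

FEATURE_KINDS = (
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "intron",
    "splice_donor",
    "splice_acceptor",
    "exon",
    "transcript_span",
    "upstream_flank",
    "downstream_flank",
)

# Conservative precedence: when two kinds claim a base, keep the kind under
# which an allele there would NOT count as non-coding/regulatory.  CDS and
# splice sites outrank UTRs, which outrank introns and flanks.
DEFAULT_PRECEDENCE = (
    "CDS",
    "splice_donor",
    "splice_acceptor",
    "five_prime_UTR",
    "three_prime_UTR",
    "intron",
    "upstream_flank",
    "downstream_flank",
)


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation input."""


@dataclass(frozen=True, order=True)
class FeatureInterval:
    """A typed, stranded genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    transcript_id: str | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end) and self.kind != "insertion_point":
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} ({self.kind})"
            )
        # splice sites are derived at exactly 2 bp; overlap resolution may
        # truncate one, so only wider intervals are structurally invalid
        if self.kind in ("splice_donor", "splice_acceptor") and self.end - self.start > 2:
            raise AnnotationError(f"splice site wider than 2 bp: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class Transcript:
    """One mRNA isoform: ordered exons, CDS segments and a strand-aware TSS.

    ``exons`` and ``cds`` are kept in transcript order (5'->3').
    """

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[FeatureInterval]
    cds: list[FeatureInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        genomic = sorted(self.exons, key=lambda f: f.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"overlapping exons in transcript {self.id}: "
                    f"{a.start}-{a.end} vs {b.start}-{b.end}"
                )
        order = (lambda f: f.start) if self.strand == "+" else (lambda f: -f.start)
        self.exons = sorted(self.exons, key=order)
        self.cds = sorted(self.cds, key=order)

    @property
    def exons_genomic(self) -> list[FeatureInterval]:
        return sorted(self.exons, key=lambda f: f.start)

    @property
    def cds_genomic(self) -> list[FeatureInterval]:
        return sorted(self.cds, key=lambda f: f.start)

    @property
    def span(self) -> tuple[int, int]:
        genomic = self.exons_genomic
        return genomic[0].start, genomic[-1].end

    @property
    def tss(self) -> int:
        """0-based position of the transcript's 5'-most base."""
        start, end = self.span
        return start if self.strand == "+" else end - 1

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def cds_length(self) -> int:
        return sum(c.length for c in self.cds)


COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class GenomeAnnotation:
    """Genome sequence plus transcript models and a per-chromosome index."""

    def __init__(
        self,
        sequences: Mapping[str, str],
        transcripts: Iterable[Transcript],
        flank_bp: int = DEFAULT_FLANK_BP,
    ) -> None:
        self.sequences: dict[str, str] = dict(sequences)
        self.transcripts: dict[str, Transcript] = {}
        self.genes: dict[str, list[str]] = {}
        self.flank_bp = flank_bp
        self._trees: dict[str, IntervalTree] = {}
        self._feature_cache: dict[str, list[FeatureInterval]] = {}
        for tx in transcripts:
            if tx.id in self.transcripts:
                raise AnnotationError(f"duplicate transcript id {tx.id}")
            if tx.chrom not in self.sequences:
                raise AnnotationError(
                    f"transcript {tx.id} references chromosome {tx.chrom} absent from FASTA"
                )
            self.transcripts[tx.id] = tx
            self.genes.setdefault(tx.gene_id, []).append(tx.id)
            start, end = tx.span
            self._trees.setdefault(tx.chrom, IntervalTree()).addi(start, end, tx.id)
        for tids in self.genes.values():
            tids.sort()

    def sequence(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise AnnotationError(f"chromosome {chrom} absent from genome")
        return self.sequences[chrom][max(start, 0) : end]

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def transcripts_near(self, chrom: str, start: int, end: int, pad: int | None = None) -> list[Transcript]:
        """All transcripts whose span, padded by ``pad`` (default flank_bp), overlaps."""
        if chrom not in self._trees:
            return []
        pad = self.flank_bp if pad is None else pad
        hits = self._trees[chrom].overlap(start - pad, end + pad)
        return sorted((self.transcripts[h.data] for h in hits), key=lambda t: t.id)

    def features(self, transcript_id: str) -> list[FeatureInterval]:
        """Derived features of one transcript (cached)."""
        if transcript_id not in self._feature_cache:
            tx = self.transcripts[transcript_id]
            self._feature_cache[transcript_id] = derive_transcript_features(
                tx, flank_bp=self.flank_bp, chrom_length=self.chrom_length(tx.chrom)
            )
        return self._feature_cache[transcript_id]

    def all_features(self, kinds: Sequence[str] | None = None) -> list[FeatureInterval]:
        out: list[FeatureInterval] = []
        for tid in sorted(self.transcripts):
            for f in self.features(tid):
                if kinds is None or f.kind in kinds:
                    out.append(f)
        return out

    def cds_sequence(self, transcript_id: str) -> str:
        """Spliced CDS in coding orientation."""
        tx = self.transcripts[transcript_id]
        parts = [self.sequence(tx.chrom, c.start, c.end) for c in tx.cds_genomic]
        seq = "".join(parts)
        return seq if tx.strand == "+" else revcomp(seq)


def derive_transcript_features(
    transcript: Transcript,
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_length: int | None = None,
) -> list[FeatureInterval]:
    """Derive CDS, UTR, intron, splice-site and flank intervals for one transcript.

    Introns are the gaps between consecutive exons; the splice donor is the
    first 2 intronic bases at each intron's 5' end (on the transcript strand)
    and the acceptor the last 2 at its 3' end.  UTRs are exon minus CDS,
    split by side relative to the CDS.  Flanks extend ``flank_bp`` beyond the
    transcript span (clipped to the chromosome).
    """
    tx = transcript
    exons = tx.exons_genomic
    out: list[FeatureInterval] = []

    def mk(start: int, end: int, kind: str) -> FeatureInterval:
        return FeatureInterval(tx.chrom, start, end, tx.strand, kind, tx.id, tx.gene_id)

    out.extend(replace(c, kind="CDS", transcript_id=tx.id, gene_id=tx.gene_id) for c in tx.cds_genomic)

    if tx.cds:
        cds_lo = tx.cds_genomic[0].start
        cds_hi = tx.cds_genomic[-1].end
        left_kind = "five_prime_UTR" if tx.strand == "+" else "three_prime_UTR"
        right_kind = "three_prime_UTR" if tx.strand == "+" else "five_prime_UTR"
        for ex in exons:
            if ex.start < cds_lo:
                out.append(mk(ex.start, min(ex.end, cds_lo), left_kind))
            if ex.end > cds_hi:
                out.append(mk(max(ex.start, cds_hi), ex.end, right_kind))

    for a, b in zip(exons, exons[1:]):
        intron = mk(a.end, b.start, "intron")
        out.append(intron)
        if tx.strand == "+":
            out.append(mk(intron.start, intron.start + 2, "splice_donor"))
            out.append(mk(intron.end - 2, intron.end, "splice_acceptor"))
        else:
            out.append(mk(intron.end - 2, intron.end, "splice_donor"))
            out.append(mk(intron.start, intron.start + 2, "splice_acceptor"))

    span_start, span_end = tx.span
    limit = chrom_length if chrom_length is not None else span_end + flank_bp
    left = (max(0, span_start - flank_bp), span_start)
    right = (span_end, min(limit, span_end + flank_bp))
    left_kind = "upstream_flank" if tx.strand == "+" else "downstream_flank"
    right_kind = "downstream_flank" if tx.strand == "+" else "upstream_flank"
    if left[0] < left[1]:
        out.append(mk(*left, left_kind))
    if right[0] < right[1]:
        out.append(mk(*right, right_kind))

    return sorted(out, key=lambda f: (f.start, f.end, f.kind))


def resolve_overlaps(
    features: Sequence[FeatureInterval],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> list[FeatureInterval]:
    """Reduce overlapping features to a disjoint set by kind precedence.

    Every output base is labelled with the highest-precedence kind that
    covered it in the input; lower-precedence intervals are truncated or
    split, never expanded.  Attribution (transcript/gene id) of a resolved
    segment follows the winning kind, ties broken by transcript id.
    """
    rank = {k: i for i, k in enumerate(precedence)}
    for f in features:
        if f.kind not in rank:
            raise AnnotationError(f"unknown feature kind in overlap resolution: {f.kind!r}")

    out: list[FeatureInterval] = []
    by_chrom: dict[str, list[FeatureInterval]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)

    for chrom in sorted(by_chrom):
        feats = by_chrom[chrom]
        bounds = sorted({f.start for f in feats} | {f.end for f in feats})
        starts = sorted(feats, key=lambda f: f.start)
        active: list[FeatureInterval] = []
        i = 0
        segments: list[tuple[int, int, FeatureInterval]] = []
        for lo, hi in zip(bounds, bounds[1:]):
            while i < len(starts) and starts[i].start <= lo:
                active.append(starts[i])
                i += 1
            active = [f for f in active if f.end > lo]
            if not active:
                continue
            covering = [f for f in active if f.start <= lo]
            if not covering:
                continue
            best = min(
                covering,
                key=lambda f: (rank[f.kind], f.transcript_id or "", f.gene_id or "", f.start),
            )
            segments.append((lo, hi, best))
        # coalesce adjacent segments with identical label + attribution
        for lo, hi, src in segments:
            prev = out[-1] if out else None
            if (
                prev is not None
                and prev.chrom == chrom
                and prev.end == lo
                and prev.kind == src.kind
                and prev.transcript_id == src.transcript_id
                and prev.gene_id == src.gene_id
                and prev.strand == src.strand
            ):
                out[-1] = replace(prev, end=hi)
            else:
                out.append(replace(src, start=lo, end=hi))
    return out


# ---------------------------------------------------------------------------
# GFF3 / FASTA / BED I/O
# ---------------------------------------------------------------------------

def read_gff3(
    annotation_path: str | Path,
    fasta_path: str | Path,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> GenomeAnnotation:
    """Read a GFF3 annotation plus its genome FASTA into a :class:`GenomeAnnotation`.

    Expects gene/mRNA/exon/CDS records with ``Parent`` links.  Coordinates are
    converted from GFF3 1-based closed to internal 0-based half-open.  UTRs,
    introns and splice sites are derived rather than read.
    """
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    problems: list[str] = []
    transcripts: list[Transcript] = []
    for mrna in db.features_of_type(("mRNA", "transcript"), order_by=("seqid", "start")):
        parents = mrna.attributes.get("Parent", [])
        if not parents:
            problems.append(f"mRNA {mrna.id} has no Parent gene")
            continue
        gene_id = parents[0]
        if mrna.seqid not in sequences:
            problems.append(f"mRNA {mrna.id} on chromosome {mrna.seqid} absent from FASTA")
            continue
        exons = []
        cds = []
        for child in db.children(mrna, featuretype=("exon", "CDS"), order_by="start"):
            iv = FeatureInterval(
                mrna.seqid, child.start - 1, child.end, mrna.strand,
                "CDS" if child.featuretype == "CDS" else "exon",
                mrna.id, gene_id,
            )
            (cds if child.featuretype == "CDS" else exons).append(iv)
        if not exons:
            problems.append(f"mRNA {mrna.id} has no exons")
            continue
        for c in cds:
            if not any(e.start <= c.start and c.end <= e.end for e in exons):
                problems.append(
                    f"CDS {c.start + 1}-{c.end} of {mrna.id} not contained in any exon"
                )
        transcripts.append(Transcript(mrna.id, gene_id, mrna.seqid, mrna.strand, exons, cds))
    if problems:
        raise AnnotationError("invalid GFF3 input:\n  " + "\n  ".join(problems))
    return GenomeAnnotation(sequences, transcripts, flank_bp=flank_bp)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS records (1-based closed, with CDS phase)."""
    lines = ["##gff-version 3"]
    for gene_id in sorted(annotation.genes):
        tids = annotation.genes[gene_id]
        txs = [annotation.transcripts[t] for t in tids]
        g_start = min(t.span[0] for t in txs)
        g_end = max(t.span[1] for t in txs)
        chrom, strand = txs[0].chrom, txs[0].strand
        lines.append(
            f"{chrom}\tregbash\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\tID={gene_id}"
        )
        for tx in txs:
            s, e = tx.span
            lines.append(
                f"{tx.chrom}\tregbash\tmRNA\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                f"ID={tx.id};Parent={gene_id}"
            )
            for ex in tx.exons_genomic:
                lines.append(
                    f"{tx.chrom}\tregbash\texon\t{ex.start + 1}\t{ex.end}\t.\t{tx.strand}\t.\t"
                    f"Parent={tx.id}"
                )
            phase_cum = 0
            for c in tx.cds:  # transcript order so phase accumulates 5'->3'
                phase = (3 - phase_cum % 3) % 3
                lines.append(
                    f"{tx.chrom}\tregbash\tCDS\t{c.start + 1}\t{c.end}\t.\t{tx.strand}\t{phase}\t"
                    f"Parent={tx.id}"
                )
                phase_cum += c.length
    Path(path).write_text("\n".join(lines) + "\n")


def write_feature_bed(features: Sequence[FeatureInterval], path: str | Path) -> None:
    """Write features as BED6 (0-based half-open; name = kind|transcript)."""
    rows = sorted(features, key=lambda f: (f.chrom, f.start, f.end, f.kind))
    with open(path, "w") as fh:
        for f in rows:
            name = f"{f.kind}|{f.transcript_id or '.'}"
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")
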