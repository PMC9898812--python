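"""Allele consequence classification.

Each allele is classified against every overlapping transcript isoform
(codon-aware for CDS substitutions, frame-aware for CDS indels, interval
lookup for splice sites, UTRs, introns and flanks) and the per-isoform calls
are aggregated to one gene-level category by a fixed severity order.  The
aggregation encodes the conservative curation direction: an allele that
changes protein sequence in ANY isoform counts as coding, never as
non-coding/regulatory.

A nominally synonymous substitution can still change the protein by creating
an ectopic splice donor (a new exonic GT on the coding strand); such alleles
are flagged and reclassified as coding at the gene level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Data.CodonTable import standard_dna_table

from .annotation import GenomeAnnotation, Transcript, revcomp
from .variants import Allele

__all__ = [
    "TranscriptConsequence",
    "ConsequenceCall",
    "classify_against_transcript",
    "flag_ectopic_splice_donor",
    "aggregate_consequences",
    "classify_alleles",
    "write_calls_tsv",
    "read_calls_tsv",
    "SEVERITY_ORDER",
    "GENE_CATEGORY_OF",
    "PROTEIN_CHANGING",
]

STOP = "*"
_CODON_TABLE = dict(standard_dna_table.forward_table)
for _c in standard_dna_table.stop_codons:
    _CODON_TABLE[_c] = STOP


def translate_codon(codon: str) -> str:
    return _CODON_TABLE.get(codon.upper(), "X")


# Most-severe first; aggregation picks the first category any isoform shows.
SEVERITY_ORDER = (
    "transcript_ablation",
    "frameshift",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "inframe_deletion",
    "inframe_insertion",
    "missense",
    "splice_donor",
    "splice_acceptor",
    "splice_unclear",
    "synonymous",
    "five_prime_UTR",
    "three_prime_UTR",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_SEV_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

PROTEIN_CHANGING = frozenset(
    {
        "transcript_ablation",
        "frameshift",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "inframe_deletion",
        "inframe_insertion",
        "missense",
    }
)

GENE_CATEGORY_OF = {
    **{c: "coding" for c in PROTEIN_CHANGING},
    "splice_donor": "splicing",
    "splice_acceptor": "splicing",
    "splice_unclear": "splicing",
    "synonymous": "synonymous",
    "five_prime_UTR": "non_coding_regulatory",
    "three_prime_UTR": "non_coding_regulatory",
    "intronic": "non_coding_regulatory",
    "upstream": "non_coding_regulatory",
    "downstream": "non_coding_regulatory",
    "intergenic": "intergenic_unassigned",
}


@dataclass(frozen=True)
class TranscriptConsequence:
    allele_id: str
    transcript_id: str | None
    category: str
    detail: str = ""
    ectopic_donor_flag: bool = False

    def __post_init__(self) -> None:
        if self.category not in _SEV_RANK:
            raise ValueError(f"unknown consequence category {self.category!r}")


@dataclass
class ConsequenceCall:
    """Gene-level call for one allele plus the per-isoform detail."""

    allele_id: str
    gene_id: str | None
    gene_category: str
    fine_category: str
    per_transcript: list[TranscriptConsequence] = field(default_factory=list)
    chrom: str = ""
    start: int = 0
    end: int = 0
    source: str = "forward_genetics"


def _cds_coordinate(tx: Transcript, pos: int) -> int | None:
    """Position in the spliced CDS (coding orientation), or None if not in CDS."""
    offset = 0
    for c in tx.cds:  # transcript order
        if c.start <= pos < c.end:
            if tx.strand == "+":
                return offset + (pos - c.start)
            return offset + (c.end - 1 - pos)
        offset += c.length
    return None


def classify_against_transcript(
    allele: Allele, transcript: Transcript, genome: GenomeAnnotation
) -> TranscriptConsequence:
    """Classify one allele against one transcript isoform.

    CDS substitutions are resolved through the codon table
    (start_lost / stop_lost / stop_gained / missense / synonymous); CDS
    indels are frameshift when the length change is not a multiple of 3,
    in-frame otherwise.  A deletion covering the whole transcript span is a
    transcript ablation.  Everything else falls through interval lookup:
    splice sites, then UTRs/introns, then flanks, then intergenic.
    """
    tx = transcript
    a_start = allele.pos
    a_end = allele.pos + 1 if allele.is_insertion else allele.end

    if allele.chrom != tx.chrom:
        return TranscriptConsequence(allele.id, tx.id, "intergenic")

    span_start, span_end = tx.span
    if allele.is_deletion and allele.pos <= span_start and allele.end >= span_end:
        return TranscriptConsequence(allele.id, tx.id, "transcript_ablation")

    in_cds = any(c.start < a_end and a_start < c.end for c in tx.cds)
    if in_cds:
        if allele.is_substitution:
            return _classify_cds_substitution(allele, tx, genome)
        net = abs(len(allele.ref) - len(allele.alt))
        if net % 3 != 0:
            return TranscriptConsequence(allele.id, tx.id, "frameshift", f"net {net} bp")
        kind = "inframe_deletion" if len(allele.ref) > len(allele.alt) else "inframe_insertion"
        return TranscriptConsequence(allele.id, tx.id, kind, f"net {net} bp")

    feats = genome.features(tx.id) if tx.id in genome.transcripts else (
        _derived(tx, genome)
    )
    by_kind: dict[str, bool] = {}
    for f in feats:
        if f.overlaps(a_start, a_end):
            by_kind[f.kind] = True
    for kind, cat in (
        ("splice_donor", "splice_donor"),
        ("splice_acceptor", "splice_acceptor"),
        ("five_prime_UTR", "five_prime_UTR"),
        ("three_prime_UTR", "three_prime_UTR"),
        ("intron", "intronic"),
        ("upstream_flank", "upstream"),
        ("downstream_flank", "downstream"),
    ):
        if by_kind.get(kind):
            return TranscriptConsequence(allele.id, tx.id, cat)
    return TranscriptConsequence(allele.id, tx.id, "intergenic")


def _derived(tx: Transcript, genome: GenomeAnnotation):
    from .annotation import derive_transcript_features

    return derive_transcript_features(tx, flank_bp=genome.flank_bp,
                                      chrom_length=genome.chrom_length(tx.chrom))


def _classify_cds_substitution(
    allele: Allele, tx: Transcript, genome: GenomeAnnotation
) -> TranscriptConsequence:
    cds_seq = genome.cds_sequence(tx.id)
    c = _cds_coordinate(tx, allele.pos)
    assert c is not None
    alt_base = allele.alt if tx.strand == "+" else revcomp(allele.alt)
    codon_idx, within = divmod(c, 3)
    ref_codon = cds_seq[3 * codon_idx : 3 * codon_idx + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa, alt_aa = translate_codon(ref_codon), translate_codon(alt_codon)
    detail = f"c.{c + 1}{cds_seq[c]}>{alt_base}|{ref_codon}>{alt_codon}|p.{ref_aa}{codon_idx + 1}{alt_aa}"

    tid = tx.id
    if codon_idx == 0 and alt_codon != ref_codon and ref_codon == "ATG":
        cat = "start_lost"
    elif ref_aa == STOP and alt_aa != STOP:
        cat = "stop_lost"
    elif alt_aa == STOP and ref_aa != STOP:
        cat = "stop_gained"
    elif ref_aa == alt_aa:
        cat = "synonymous"
    else:
        cat = "missense"
    tc = TranscriptConsequence(allele.id, tid, cat, detail)
    if cat == "synonymous":
        flag = flag_ectopic_splice_donor(allele, tx, genome)
        if flag:
            tc = TranscriptConsequence(allele.id, tid, cat, detail, ectopic_donor_flag=True)
    return tc


def flag_ectopic_splice_donor(
    allele: Allele, transcript: Transcript, genome: GenomeAnnotation
) -> bool:
    """Does a synonymous substitution create a new exonic GT on the coding strand?

    Scans a window of the edit (one reference base of context on each side)
    in coding orientation and reports True iff the mutated window contains a
    GT dinucleotide at an offset where the reference window does not.
    Intended for substitutions already classified synonymous; any other call
    is a contract violation.
    """
    if not allele.is_substitution:
        raise ValueError("ectopic-donor flag is defined for substitutions only")
    chrom_len = genome.chrom_length(allele.chrom)
    lo = max(0, allele.pos - 1)
    hi = min(chrom_len, allele.pos + len(allele.ref) + 1)
    ref_window = genome.sequence(allele.chrom, lo, hi)
    edit_at = allele.pos - lo
    alt_window = ref_window[:edit_at] + allele.alt + ref_window[edit_at + len(allele.ref) :]
    if transcript.strand == "-":
        ref_window, alt_window = revcomp(ref_window), revcomp(alt_window)
    ref_hits = {i for i in range(len(ref_window) - 1) if ref_window[i : i + 2] == "GT"}
    alt_hits = {i for i in range(len(alt_window) - 1) if alt_window[i : i + 2] == "GT"}
    return bool(alt_hits - ref_hits)


def aggregate_consequences(
    per_transcript: Sequence[TranscriptConsequence],
) -> tuple[str, str, str | None]:
    """Aggregate per-isoform calls: (gene_category, fine_category, winning tid).

    The winning fine category is the most severe across isoforms (ties by
    lexicographic transcript id).  A synonymous winner with an ectopic-donor
    flag on any isoform is reclassified coding at the gene level.
    """
    if not per_transcript:
        raise ValueError("aggregate_consequences requires at least one record")
    winner = min(
        per_transcript,
        key=lambda tc: (_SEV_RANK[tc.category], tc.transcript_id or "~"),
    )
    fine = winner.category
    gene_category = GENE_CATEGORY_OF[fine]
    if fine == "synonymous" and any(
        tc.category == "synonymous" and tc.ectopic_donor_flag for tc in per_transcript
    ):
        gene_category = "coding"
    return gene_category, fine, winner.transcript_id


def classify_alleles(
    alleles: Sequence[Allele],
    genome: GenomeAnnotation,
    per_gene: bool = False,
) -> list[ConsequenceCall]:
    """Classify every allele; one call per allele (or per overlapped gene).

    By default each allele yields exactly one call — the most severe
    consequence across all genes and isoforms it touches — so that category
    counts partition the allele set.  With ``per_gene=True`` an allele
    overlapping several genes is reported once per gene.
    """
    calls: list[ConsequenceCall] = []
    for allele in alleles:
        if allele.chrom not in genome.sequences:
            warnings.warn(f"allele {allele.id}: chromosome {allele.chrom} not annotated")
            txs: list[Transcript] = []
        else:
            q_end = max(allele.end, allele.pos + 1)
            txs = genome.transcripts_near(allele.chrom, allele.pos, q_end)
        per_tc = [classify_against_transcript(allele, tx, genome) for tx in txs]
        per_tc = [tc for tc in per_tc if tc.category != "intergenic"] or [
            TranscriptConsequence(allele.id, None, "intergenic")
        ]
        groups: dict[str | None, list[TranscriptConsequence]]
        if per_gene:
            groups = {}
            for tc in per_tc:
                gid = genome.transcripts[tc.transcript_id].gene_id if tc.transcript_id else None
                groups.setdefault(gid, []).append(tc)
        else:
            groups = {None: per_tc}
        for gid in sorted(groups, key=lambda g: g or "~"):
            recs = groups[gid]
            gene_category, fine, win_tid = aggregate_consequences(recs)
            gene_id = gid
            if gene_id is None and win_tid is not None:
                gene_id = genome.transcripts[win_tid].gene_id
            calls.append(
                ConsequenceCall(
                    allele_id=allele.id,
                    gene_id=gene_id,
                    gene_category=gene_category,
                    fine_category=fine,
                    per_transcript=recs,
                    chrom=allele.chrom,
                    start=allele.pos,
                    end=max(allele.end, allele.pos + (0 if allele.is_insertion else 1)),
                    source=allele.source,
                )
            )
    return calls


def write_calls_tsv(calls: Sequence[ConsequenceCall], path: str | Path) -> None:
    """One row per call: ids, categories and per-isoform detail."""
    with open(path, "w") as fh:
        fh.write("#regbash-table\tv1\tconsequence_calls\n")
        fh.write(
            "allele_id\tgene_id\tgene_category\tfine_category\tchrom\tstart\tend\t"
            "source\tper_transcript\n"
        )
        for c in calls:
            detail = ";".join(
                f"{tc.transcript_id or '.'}:{tc.category}"
                + ("!ectopic_donor" if tc.ectopic_donor_flag else "")
                for tc in c.per_transcript
            )
            fh.write(
                f"{c.allele_id}\t{c.gene_id or '.'}\t{c.gene_category}\t{c.fine_category}\t"
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.source}\t{detail}\n"
            )


def read_calls_tsv(path: str | Path) -> list[ConsequenceCall]:
    calls: list[ConsequenceCall] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            per_tc = []
            if row.get("per_transcript"):
                for item in row["per_transcript"].split(";"):
                    tid_cat, _, _flag = item.partition("!")
                    tid, _, cat = tid_cat.rpartition(":")
                    per_tc.append(
                        TranscriptConsequence(
                            row["allele_id"], None if tid == "." else tid, cat,
                            ectopic_donor_flag=bool(_flag),
                        )
                    )
            calls.append(
                ConsequenceCall(
                    allele_id=row["allele_id"],
                    gene_id=None if row["gene_id"] == "." else row["gene_id"],
                    gene_category=row["gene_category"],
                    fine_category=row["fine_category"],
                    per_transcript=per_tc,
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    source=row.get("source", "forward_genetics"),
                )
            )
    return calls
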