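"""Allele records: TSV/VCF input, genome validation, category-wise BED export.

An allele is a single sequence change — substitution, insertion or deletion —
with provenance (forward genetics, CRISPR editing, or a reporter construct).
The input dialect is a simple TSV because the upstream source is a curated
spreadsheet, not a variant-calling pipeline; a VCF reader mapping
POS/REF/ALT identically is provided as a convenience.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .annotation import GenomeAnnotation
    from .consequence import ConsequenceCall

__all__ = [
    "Allele",
    "AlleleLoadReport",
    "read_alleles",
    "write_allele_tsv",
    "write_bed",
    "left_align",
    "SOURCES",
]

SOURCES = ("forward_genetics", "crispr", "reporter")

_EMPTY = {"", ".", "-"}


@dataclass(frozen=True)
class Allele:
    """One sequence change, 0-based internally.

    ``ref`` is empty for an insertion (inserted before ``pos``); ``alt`` is
    empty for a deletion.  A substitution has ``|ref| == |alt| == 1``.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    source: str = "forward_genetics"
    gene_hint: str | None = None
    phenotype_note: str = ""

    def __post_init__(self) -> None:
        if not self.ref and not self.alt:
            raise ValueError(f"allele {self.id}: ref and alt cannot both be empty")

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_deletion(self) -> bool:
        return bool(self.ref) and not self.alt

    @property
    def is_insertion(self) -> bool:
        return bool(self.alt) and not self.ref

    @property
    def end(self) -> int:
        """End (exclusive) of the affected reference span; == pos for insertions."""
        return self.pos + len(self.ref)


@dataclass
class AlleleLoadReport:
    """Per-file load summary: rejected rows and collapsed duplicates."""

    n_loaded: int = 0
    n_duplicates: int = 0
    rejects: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.rejects


def left_align(allele: Allele, genome: "GenomeAnnotation") -> Allele:
    """Left-align an indel against the genome (no-op for substitutions).

    Shifts the event left while the base preceding it equals the last base of
    the inserted/deleted sequence — the conventional normalization for
    ambiguously placed indels in repeats.
    """
    if allele.is_substitution or (allele.ref and allele.alt):
        return allele
    seq = allele.ref if allele.is_deletion else allele.alt
    pos = allele.pos
    chrom_seq = genome.sequences[allele.chrom]
    while pos > 0 and chrom_seq[pos - 1] == seq[-1]:
        seq = chrom_seq[pos - 1] + seq[:-1]
        pos -= 1
    if allele.is_deletion:
        return replace(allele, pos=pos, ref=seq)
    return replace(allele, pos=pos, alt=seq)


def read_alleles(
    path: str | Path, genome: "GenomeAnnotation"
) -> tuple[list[Allele], AlleleLoadReport]:
    """Read a TSV of alleles (header: chrom, pos, id, ref, alt, source).

    File positions are 1-based; internal positions 0-based.  Rows whose ref
    does not match the genome are rejected (loading continues; the report
    lists them with line numbers).  Exact duplicates are collapsed with a
    warning count.  Indels are left-aligned after validation.
    """
    report = AlleleLoadReport()
    seen: set[tuple[str, int, str, str, str]] = set()
    alleles: list[Allele] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                missing = {"chrom", "pos", "id", "ref", "alt", "source"} - set(header)
                if missing:
                    raise ValueError(f"{path}: missing columns {sorted(missing)}")
                continue
            row = dict(zip(header, fields))
            ref = "" if row["ref"] in _EMPTY else row["ref"].upper()
            alt = "" if row["alt"] in _EMPTY else row["alt"].upper()
            chrom = row["chrom"]
            try:
                pos = int(row["pos"]) - 1
            except ValueError:
                report.rejects.append(f"line {lineno}: non-integer pos {row['pos']!r}")
                continue
            if chrom not in genome.sequences:
                report.rejects.append(f"line {lineno}: unknown chromosome {chrom!r}")
                continue
            if ref:
                observed = genome.sequence(chrom, pos, pos + len(ref))
                if observed != ref:
                    report.rejects.append(
                        f"line {lineno}: ref mismatch at {chrom}:{pos + 1} "
                        f"(file {ref!r}, genome {observed!r})"
                    )
                    continue
            key = (chrom, pos, ref, alt, row["id"])
            if key in seen:
                report.n_duplicates += 1
                continue
            seen.add(key)
            allele = Allele(
                id=row["id"],
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                source=row.get("source", "forward_genetics"),
                gene_hint=row.get("gene_hint") or None,
            )
            alleles.append(left_align(allele, genome))
            report.n_loaded += 1
    if report.n_duplicates:
        warnings.warn(f"{path}: collapsed {report.n_duplicates} duplicate allele rows")
    return alleles, report


def write_allele_tsv(alleles: Sequence[Allele], path: str | Path) -> None:
    """Write alleles back to the TSV dialect (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tid\tref\talt\tsource\tgene_hint\n")
        for a in alleles:
            fh.write(
                f"{a.chrom}\t{a.pos + 1}\t{a.id}\t{a.ref or '-'}\t{a.alt or '-'}\t"
                f"{a.source}\t{a.gene_hint or ''}\n"
            )


def write_bed(calls: Sequence["ConsequenceCall"], out_dir: str | Path) -> list[Path]:
    """Export one BED file per non-empty fine category.

    Records are 0-based half-open, name column = allele id, sorted by
    (chrom, start, id).  Returns the written paths.  Insertions are emitted
    as the single base before which the insertion occurs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_cat: dict[str, list["ConsequenceCall"]] = {}
    for call in calls:
        by_cat.setdefault(call.fine_category, []).append(call)
    written: list[Path] = []
    for cat in sorted(by_cat):
        path = out_dir / f"{cat}.bed"
        rows = sorted(by_cat[cat], key=lambda c: (c.chrom, c.start, c.allele_id))
        with open(path, "w") as fh:
            for c in rows:
                end = max(c.end, c.start + 1)
                fh.write(f"{c.chrom}\t{c.start}\t{end}\t{c.allele_id}\n")
        written.append(path)
    return written
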