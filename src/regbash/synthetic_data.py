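"""Synthetic genomes, annotations, alleles and study tables with known truth.

Every downstream stage (annotation parsing, consequence classification,
curation, summary statistics) is exercisable against fixtures generated
here, with ground-truth labels forced by construction: a missense allele is
a non-synonymous, non-stop substitution inside the CDS of every isoform; a
splice-donor allele sits in the GT of an intron shared by all isoforms; an
intergenic allele lies beyond the flank of every gene; and so on.

Generated gene models are biologically valid by construction: each CDS
starts with ATG, ends with a stop, has no internal stop and a length
divisible by 3; introns begin GT and end AG.  Multi-isoform genes share
exons and differ in their translation start (a downstream in-frame ATG), so
the same base can be 5'UTR in one isoform and coding in another — exactly
the situation the any-isoform exclusion rule exists for.

All randomness flows from numpy Generators derived from one integer seed;
identical config + seed gives byte-identical FASTA/GFF3/TSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import (
    DEFAULT_FLANK_BP,
    FeatureInterval,
    GenomeAnnotation,
    Transcript,
    revcomp,
    write_gff3,
)
from .consequence import SEVERITY_ORDER, PROTEIN_CHANGING
from .curation import CuratedRecord, StudyRecord, round_distance
from .variants import Allele, left_align

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "PlacementError",
    "CategoryPlacementError",
    "generate_toy_genome",
    "generate_alleles",
    "generate_study_tables",
    "write_fasta",
    "synthetic_catalogue_tables",
    "SUPPORTED_CATEGORIES",
    "DEFAULT_CATEGORY_PROPORTIONS",
]

_SEV_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

SUPPORTED_CATEGORIES = frozenset(SEVERITY_ORDER) - {"splice_unclear"}
# "other" spreads over the rarer protein-changing classes
_OTHER_POOL = ("start_lost", "stop_lost", "frameshift", "inframe_deletion", "inframe_insertion")

# Default allele mixture mirrors a forward-genetics allele catalogue:
# missense and stop gains dominate, splice-site hits follow, genuinely
# regulatory changes are rare.
DEFAULT_CATEGORY_PROPORTIONS = {
    "missense": 0.474,
    "stop_gained": 0.277,
    "other": 0.053,
    "splice_acceptor": 0.108,
    "splice_donor": 0.046,
    "synonymous": 0.005,
    "five_prime_UTR": 0.005,
    "three_prime_UTR": 0.005,
    "intronic": 0.005,
    "upstream": 0.005,
    "downstream": 0.002,
    "intergenic": 0.015,
}

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)
_AA = {}
from Bio.Data.CodonTable import standard_dna_table as _tbl

_AA.update(_tbl.forward_table)
for _s in _tbl.stop_codons:
    _AA[_s] = "*"


class PlacementError(ValueError):
    """Genes cannot be placed in the configured genome."""


class CategoryPlacementError(ValueError):
    """A requested allele category has no valid site in the annotation."""


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults give a small but rich test genome."""

    n_chromosomes: int = 2
    chrom_length: int = 150_000
    n_genes: int = 14
    isoforms_per_gene: tuple[int, int] = (1, 2)
    intron_count: tuple[int, int] = (2, 3)
    utr5_length: tuple[int, int] = (60, 150)
    utr3_length: tuple[int, int] = (80, 200)
    cds_codons: tuple[int, int] = (90, 150)  # internal codons, excl. start/stop
    intron_length: tuple[int, int] = (45, 120)
    intergenic_gap: tuple[int, int] = (10_500, 13_000)
    strand_mix: float = 0.5  # fraction of genes on the minus strand
    flank_bp: int = DEFAULT_FLANK_BP
    overlapping_genes: bool = False
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    n_alleles: int = 200
    # study/element tables
    n_elements: int = 100
    n_studies: int = 99
    n_reporter_studies: int = 50
    n_forward_studies: int = 35
    distance_median: float = 1200.0
    distance_sigma: float = 0.8
    down_probability: dict[str, float] = field(
        default_factory=lambda: {
            "transcriptional_cis_regulatory": 0.8,
            "five_prime_UTR": 0.8,
            "three_prime_UTR": 0.25,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_proportions.values())
        if any(v < 0 for v in self.category_proportions.values()):
            raise ValueError("category proportions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions must sum to 1 (got {total})")
        for name in ("isoforms_per_gene", "intron_count", "utr5_length", "utr3_length",
                     "cds_codons", "intron_length", "intergenic_gap"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0 or (name not in ("intron_count",) and hi <= 0):
                raise ValueError(f"invalid range for {name}: {(lo, hi)}")
        if not 0.0 <= self.strand_mix <= 1.0:
            raise ValueError("strand_mix must be in [0, 1]")
        unknown = set(self.category_proportions) - SUPPORTED_CATEGORIES - {"other"}
        if unknown:
            raise ValueError(f"unsupported consequence categories: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """True labels/parameters behind one synthetic dataset."""

    allele_categories: dict[str, str] = field(default_factory=dict)
    allele_requested: dict[str, str] = field(default_factory=dict)
    element_distances: dict[str, int] = field(default_factory=dict)
    study_conclusions: dict[str, str] = field(default_factory=dict)
    study_mutations: dict[str, int] = field(default_factory=dict)
    technique_totals: dict[str, int] = field(default_factory=dict)
    technique_means: dict[str, float] = field(default_factory=dict)
    distance_median: float | None = None


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _build_gene(rng: np.random.Generator, cfg: SyntheticConfig) -> dict:
    """One gene in local plus-sense coordinates (flipped later if minus)."""
    u5 = int(rng.integers(cfg.utr5_length[0], cfg.utr5_length[1] + 1))
    u3 = int(rng.integers(cfg.utr3_length[0], cfg.utr3_length[1] + 1))
    k = int(rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1))
    codons = ["ATG"] + [
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), size=k)
    ] + [_STOPS[int(rng.integers(0, 3))]]

    n_iso = int(rng.integers(cfg.isoforms_per_gene[0], cfg.isoforms_per_gene[1] + 1))
    alt_start_codons: list[int] = []
    if n_iso > 1 and k >= 12:
        picks = sorted(
            int(x) for x in rng.choice(np.arange(4, k - 4), size=n_iso - 1, replace=False)
        )
        for j in picks:
            codons[j] = "ATG"
        alt_start_codons = picks
    cds_seq = "".join(codons)
    cds_len = len(cds_seq)

    n_int = int(rng.integers(cfg.intron_count[0], cfg.intron_count[1] + 1))
    cuts: list[int] = []
    if n_int:
        lo, hi = 12, cds_len - 12
        while True:
            cand = sorted(int(x) for x in rng.integers(lo, hi, size=n_int))
            if len(set(cand)) == n_int and all(b - a >= 12 for a, b in zip(cand, cand[1:])):
                cuts = cand
                break
    introns = [
        "GT" + _rand_seq(rng, int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1)) - 4) + "AG"
        for _ in cuts
    ]

    # assemble local sequence and coordinates
    seq_parts = [_rand_seq(rng, u5)]
    exon_ivs: list[tuple[int, int]] = []
    cds_ivs: list[tuple[int, int]] = []
    cursor = u5
    exon_start = 0
    pieces = []
    prev = 0
    for c in cuts:
        pieces.append(cds_seq[prev:c])
        prev = c
    pieces.append(cds_seq[prev:])
    cds_coord_to_local: dict[int, int] = {}
    coord = 0
    for i, piece in enumerate(pieces):
        seq_parts.append(piece)
        cds_ivs.append((cursor, cursor + len(piece)))
        for off in range(len(piece)):
            cds_coord_to_local[coord + off] = cursor + off
        coord += len(piece)
        cursor += len(piece)
        if i < len(introns):
            exon_ivs.append((exon_start, cursor))
            seq_parts.append(introns[i])
            cursor += len(introns[i])
            exon_start = cursor
    seq_parts.append(_rand_seq(rng, u3))
    cursor += u3
    exon_ivs.append((exon_start, cursor))
    seq = "".join(seq_parts)
    assert len(seq) == cursor

    isoform_cds_starts = [0] + [3 * j for j in alt_start_codons]
    isoforms = []
    for m, cstart in enumerate(isoform_cds_starts[:n_iso]):
        local_start = cds_coord_to_local[cstart]
        ivs = []
        for s, e in cds_ivs:
            if e <= local_start:
                continue
            ivs.append((max(s, local_start), e))
        isoforms.append({"cds": ivs, "suffix": m + 1})
    return {
        "length": cursor,
        "seq": seq,
        "exons": exon_ivs,
        "isoforms": isoforms,
        "u3": u3,
        "u5": u5,
    }


def generate_toy_genome(config: SyntheticConfig) -> tuple[dict[str, str], GenomeAnnotation]:
    """Generate chromosome sequences plus a consistent annotation.

    Genes are laid out left to right with intergenic gaps wide enough that
    flank regions of neighbouring genes do not claim each other's territory
    (unless ``overlapping_genes`` is set, in which case every second gene is
    pulled back so its leading region overlaps the previous gene's 3'UTR —
    the situation conservative overlap resolution exists for).  Raises
    :class:`PlacementError` when the genome cannot hold the requested genes.
    """
    rng = np.random.default_rng([config.seed, 0])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_seqs = {c: list(_rand_seq(rng, config.chrom_length)) for c in chrom_names}
    cursors = {c: 0 for c in chrom_names}
    transcripts: list[Transcript] = []
    chrom_idx = 0
    prev_gene: dict | None = None

    for gi in range(config.n_genes):
        gene = _build_gene(rng, config)
        minus = bool(rng.random() < config.strand_mix)
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        placed = False
        overlap_this = (
            config.overlapping_genes and prev_gene is not None and gi % 2 == 1
            and prev_gene["chrom_idx"] == chrom_idx
        )
        while chrom_idx < len(chrom_names):
            chrom = chrom_names[chrom_idx]
            offset = cursors[chrom] + gap
            if overlap_this and prev_gene is not None:
                # pull back so our head overlaps the tail (3'UTR) of the
                # previous plus-strand gene by a margin inside its 3'UTR
                depth = min(prev_gene["u3"] - 10, gene["u5"] + 30)
                if depth > 0 and not prev_gene["minus"] and not minus:
                    offset = prev_gene["end"] - depth
            if offset + gene["length"] <= config.chrom_length:
                placed = True
                break
            chrom_idx += 1
            overlap_this = False
        if not placed:
            raise PlacementError(
                f"cannot place gene {gi + 1} of {config.n_genes}: "
                f"chromosomes of {config.chrom_length} bp are exhausted"
            )
        chrom = chrom_names[chrom_idx]
        L = gene["length"]
        seq = gene["seq"]
        exons = gene["exons"]
        isoforms = gene["isoforms"]
        if minus:
            seq = revcomp(seq)
            exons = sorted((L - e, L - s) for s, e in exons)
            isoforms = [
                {"cds": sorted((L - e, L - s) for s, e in iso["cds"]), "suffix": iso["suffix"]}
                for iso in isoforms
            ]
        chrom_seqs[chrom][offset : offset + L] = list(seq)
        gene_id = f"g{gi + 1:04d}"
        strand = "-" if minus else "+"
        for iso in isoforms:
            tid = f"{gene_id}.{iso['suffix']}"
            ex = [
                FeatureInterval(chrom, offset + s, offset + e, strand, "exon", tid, gene_id)
                for s, e in exons
            ]
            cd = [
                FeatureInterval(chrom, offset + s, offset + e, strand, "CDS", tid, gene_id)
                for s, e in iso["cds"]
            ]
            transcripts.append(Transcript(tid, gene_id, chrom, strand, ex, cd))
        cursors[chrom] = max(cursors[chrom], offset + L)
        prev_gene = {
            "end": offset + L,
            "u3": gene["u3"],
            "minus": minus,
            "chrom_idx": chrom_idx,
        }

    sequences = {c: "".join(s) for c, s in chrom_seqs.items()}
    annotation = GenomeAnnotation(sequences, transcripts, flank_bp=config.flank_bp)
    return sequences, annotation


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Allele generation
# ---------------------------------------------------------------------------

def _apportion(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment: counts match proportions within 1."""
    keys = sorted(proportions)
    raw = {k: proportions[k] * n for k in keys}
    base = {k: math.floor(raw[k]) for k in keys}
    remainder = n - sum(base.values())
    order = sorted(keys, key=lambda k: (-(raw[k] - base[k]), k))
    for k in order[:remainder]:
        base[k] += 1
    return base


# worst-case severity a foreign feature kind could impose on an allele there
_FOREIGN_WORST = {
    "CDS": _SEV_RANK["frameshift"],
    "splice_donor": _SEV_RANK["splice_donor"],
    "splice_acceptor": _SEV_RANK["splice_acceptor"],
    "five_prime_UTR": _SEV_RANK["five_prime_UTR"],
    "three_prime_UTR": _SEV_RANK["three_prime_UTR"],
    "intron": _SEV_RANK["intronic"],
    "upstream_flank": _SEV_RANK["upstream"],
    "downstream_flank": _SEV_RANK["downstream"],
}
_KIND_CATEGORY = {
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "intron": "intronic",
    "upstream_flank": "upstream",
    "downstream_flank": "downstream",
}


class _SiteFinder:
    """Deterministic search for genomic sites that force a given category."""

    def __init__(self, ann: GenomeAnnotation, rng: np.random.Generator, flank: int):
        self.ann = ann
        self.rng = rng
        self.flank = flank
        self.used: set[tuple[str, int, str]] = set()
        self.gene_ids = sorted(ann.genes)

    # -- geometry helpers ---------------------------------------------------

    def _foreign_ok(self, gene_id: str | None, chrom: str, start: int, end: int,
                    target_cat: str) -> bool:
        target_rank = _SEV_RANK[target_cat]
        for tx in self.ann.transcripts_near(chrom, start, end, pad=self.flank):
            if gene_id is not None and tx.gene_id == gene_id:
                continue
            for f in self.ann.features(tx.id):
                if f.kind in ("exon", "transcript_span"):
                    continue
                if f.overlaps(start, end):
                    worst = _FOREIGN_WORST[f.kind]
                    same = _KIND_CATEGORY.get(f.kind) == target_cat
                    if worst <= target_rank and not same:
                        return False
        return True

    def _positions(self, gene_id: str, kind: str, common: bool = True) -> list[int]:
        sets = []
        for tid in self.ann.genes[gene_id]:
            s: set[int] = set()
            for f in self.ann.features(tid):
                if f.kind == kind:
                    s.update(range(f.start, f.end))
            sets.append(s)
        merged = set.intersection(*sets) if common else set.union(*sets)
        return sorted(merged)

    def _claim(self, chrom: str, pos: int, alt: str) -> bool:
        key = (chrom, pos, alt)
        if key in self.used:
            return False
        self.used.add(key)
        return True

    def _shuffled_genes(self) -> list[str]:
        idx = self.rng.permutation(len(self.gene_ids))
        return [self.gene_ids[i] for i in idx]

    # -- codon machinery ----------------------------------------------------

    def _cds_layout(self, gene_id: str):
        """Minimal-CDS isoform + coding-order genomic positions + start codons."""
        txs = [self.ann.transcripts[t] for t in self.ann.genes[gene_id]]
        tx = min(txs, key=lambda t: t.cds_length())
        positions: list[int] = []
        for c in tx.cds:
            r = range(c.start, c.end) if tx.strand == "+" else range(c.end - 1, c.start - 1, -1)
            positions.extend(r)
        start_positions = set()
        for t in txs:
            first = t.cds[0]
            if t.strand == "+":
                start_positions.update(range(first.start, min(first.start + 3, first.end)))
            else:
                start_positions.update(range(max(first.end - 3, first.start), first.end))
        return tx, positions, start_positions

    def _codon(self, tx: Transcript, positions: list[int], idx: int) -> str:
        bases = []
        chrom_seq = self.ann.sequences[tx.chrom]
        for g in positions[3 * idx : 3 * idx + 3]:
            b = chrom_seq[g]
            bases.append(b if tx.strand == "+" else revcomp(b))
        return "".join(bases)

    def _creates_gt(self, tx: Transcript, pos: int, alt_genomic: str) -> bool:
        chrom_seq = self.ann.sequences[tx.chrom]
        lo, hi = max(0, pos - 1), min(len(chrom_seq), pos + 2)
        ref_w = chrom_seq[lo:hi]
        alt_w = ref_w[: pos - lo] + alt_genomic + ref_w[pos - lo + 1 :]
        if tx.strand == "-":
            ref_w, alt_w = revcomp(ref_w), revcomp(alt_w)
        ref_hits = {i for i in range(len(ref_w) - 1) if ref_w[i : i + 2] == "GT"}
        alt_hits = {i for i in range(len(alt_w) - 1) if alt_w[i : i + 2] == "GT"}
        return bool(alt_hits - ref_hits)

    # -- per-category site search -------------------------------------------

    def cds_substitution(self, category: str) -> tuple[str, int, str, str] | None:
        """Find (chrom, pos, ref, alt) forcing a coding substitution category."""
        for gene_id in self._shuffled_genes():
            tx, positions, start_positions = self._cds_layout(gene_id)
            n_codons = len(positions) // 3
            if category == "start_lost":
                candidates = [0]
            elif category == "stop_lost":
                candidates = [n_codons - 1]
            else:
                candidates = list(self.rng.permutation(np.arange(1, n_codons - 1)))
            for ci in candidates:
                codon = self._codon(tx, positions, int(ci))
                if category not in ("start_lost", "stop_lost"):
                    if any(positions[3 * int(ci) + w] in start_positions for w in range(3)):
                        continue
                for w in self.rng.permutation(3):
                    w = int(w)
                    g = positions[3 * int(ci) + w]
                    ref_coding = codon[w]
                    for alt_coding in self.rng.permutation(list(_BASES)):
                        if alt_coding == ref_coding:
                            continue
                        alt_codon = codon[:w] + alt_coding + codon[w + 1 :]
                        ref_aa, alt_aa = _AA[codon], _AA[alt_codon]
                        ok = False
                        if category == "synonymous":
                            ok = ref_aa == alt_aa and ref_aa != "*"
                        elif category == "missense":
                            ok = ref_aa != alt_aa and "*" not in (ref_aa, alt_aa)
                        elif category == "stop_gained":
                            ok = alt_aa == "*" and ref_aa != "*"
                        elif category == "stop_lost":
                            ok = ref_aa == "*" and alt_aa != "*"
                        elif category == "start_lost":
                            ok = True  # any change to the start codon
                        if not ok:
                            continue
                        ref_g = self.ann.sequences[tx.chrom][g]
                        alt_g = alt_coding if tx.strand == "+" else revcomp(alt_coding)
                        if category == "synonymous" and self._creates_gt(tx, g, alt_g):
                            continue
                        if not self._foreign_ok(gene_id, tx.chrom, g, g + 1, category):
                            continue
                        if not self._claim(tx.chrom, g, alt_g):
                            continue
                        return tx.chrom, g, ref_g, alt_g
        return None

    def region_substitution(self, category: str) -> tuple[str, int, str, str] | None:
        """Substitution inside a shared non-coding feature of some gene."""
        kind = {
            "splice_donor": "splice_donor",
            "splice_acceptor": "splice_acceptor",
            "five_prime_UTR": "five_prime_UTR",
            "three_prime_UTR": "three_prime_UTR",
            "intronic": "intron",
        }[category]
        for gene_id in self._shuffled_genes():
            positions = self._positions(gene_id, kind)
            if category == "intronic":
                donors = set(self._positions(gene_id, "splice_donor", common=False))
                accept = set(self._positions(gene_id, "splice_acceptor", common=False))
                positions = [p for p in positions if p not in donors and p not in accept]
            if category in ("five_prime_UTR", "three_prime_UTR"):
                # stay clear of intron edges; UTR positions are exonic already
                cds = set(self._positions(gene_id, "CDS", common=False))
                positions = [p for p in positions if p not in cds]
            if not positions:
                continue
            chrom = self.ann.transcripts[self.ann.genes[gene_id][0]].chrom
            for i in self.rng.permutation(len(positions)):
                p = positions[int(i)]
                ref = self.ann.sequences[chrom][p]
                for alt in self.rng.permutation(list(_BASES)):
                    if alt == ref:
                        continue
                    if not self._foreign_ok(gene_id, chrom, p, p + 1, category):
                        break
                    if self._claim(chrom, p, alt):
                        return chrom, p, ref, alt
        return None

    def flank_substitution(self, category: str) -> tuple[str, int, str, str] | None:
        kind = "upstream_flank" if category == "upstream" else "downstream_flank"
        for gene_id in self._shuffled_genes():
            positions = self._positions(gene_id, kind)
            if not positions:
                continue
            chrom = self.ann.transcripts[self.ann.genes[gene_id][0]].chrom
            for i in self.rng.permutation(len(positions))[:200]:
                p = positions[int(i)]
                if not self._foreign_ok(gene_id, chrom, p, p + 1, category):
                    continue
                ref = self.ann.sequences[chrom][p]
                alt = str(self.rng.choice([b for b in _BASES if b != ref]))
                if self._claim(chrom, p, alt):
                    return chrom, p, ref, alt
        return None

    def intergenic_substitution(self) -> tuple[str, int, str, str] | None:
        chroms = sorted(self.ann.sequences)
        for _ in range(500):
            chrom = chroms[int(self.rng.integers(0, len(chroms)))]
            p = int(self.rng.integers(0, len(self.ann.sequences[chrom])))
            if not self._foreign_ok(None, chrom, p, p + 1, "intergenic"):
                continue
            ref = self.ann.sequences[chrom][p]
            alt = str(self.rng.choice([b for b in _BASES if b != ref]))
            if self._claim(chrom, p, alt):
                return chrom, p, ref, alt
        return None

    def cds_indel(self, category: str) -> tuple[str, int, str, str] | None:
        """Indel inside the common CDS, safely inside one CDS exon."""
        for gene_id in self._shuffled_genes():
            tx, positions, start_positions = self._cds_layout(gene_id)
            n_codons = len(positions) // 3
            order = list(self.rng.permutation(np.arange(2, n_codons - 2)))
            for ci in order:
                ci = int(ci)
                span = positions[3 * ci : 3 * ci + 4]  # codon + next base
                step = 1 if tx.strand == "+" else -1
                contiguous = all(b == a + step for a, b in zip(span, span[1:]))
                if not contiguous:
                    continue
                if any(p in start_positions for p in span):
                    continue
                chrom_seq = self.ann.sequences[tx.chrom]
                if category == "frameshift":
                    length = int(self.rng.choice([1, 2, 4]))
                    pos = min(span[0], span[-1])
                    ref, alt = chrom_seq[pos : pos + length], ""
                elif category == "inframe_deletion":
                    # whole non-start, non-stop codon; forbid left-alignment
                    # shifts so exactly one residue is removed
                    pos = min(span[0], span[2])
                    ref, alt = chrom_seq[pos : pos + 3], ""
                    if pos > 0 and chrom_seq[pos - 1] == ref[-1]:
                        continue
                else:  # inframe_insertion: one codon at a codon boundary
                    codon_ins = _NONSTOP_CODONS[int(self.rng.integers(0, len(_NONSTOP_CODONS)))]
                    if tx.strand == "+":
                        pos, alt = span[0], codon_ins
                    else:
                        pos, alt = span[0] + 1, revcomp(codon_ins)
                    ref = ""
                    if pos > 0 and chrom_seq[pos - 1] == alt[-1]:
                        continue
                end = pos + max(len(ref), 1)
                if not self._foreign_ok(gene_id, tx.chrom, pos, end, category):
                    continue
                trial = Allele(id="_trial", chrom=tx.chrom, pos=pos, ref=ref, alt=alt)
                aligned = left_align(trial, self.ann)
                cds_pos = set(positions)
                a_span = range(aligned.pos, max(aligned.end, aligned.pos + 1))
                if not all(p in cds_pos for p in a_span):
                    continue
                # insertions must land between two coding bases, not at an
                # exon edge where the new bases would fall into the intron
                if not ref and (aligned.pos - 1) not in cds_pos:
                    continue
                if any(p in start_positions for p in a_span):
                    continue
                if not self._claim(tx.chrom, pos, alt or "-"):
                    continue
                return tx.chrom, pos, ref, alt
        return None

    def ablation_deletion(self) -> tuple[str, int, str, str] | None:
        for gene_id in self._shuffled_genes():
            txs = [self.ann.transcripts[t] for t in self.ann.genes[gene_id]]
            chrom = txs[0].chrom
            lo = min(t.span[0] for t in txs) - 12
            hi = max(t.span[1] for t in txs) + 12
            if lo < 0 or hi > len(self.ann.sequences[chrom]):
                continue
            clash = any(
                tx.gene_id != gene_id and tx.span[0] < hi and lo < tx.span[1]
                for tx in self.ann.transcripts_near(chrom, lo, hi, pad=0)
            )
            if clash:
                continue
            ref = self.ann.sequences[chrom][lo:hi]
            if self._claim(chrom, lo, "-del"):
                return chrom, lo, ref, ""
        return None


def generate_alleles(
    annotation: GenomeAnnotation, config: SyntheticConfig
) -> tuple[list[Allele], GroundTruth]:
    """Place ``config.n_alleles`` alleles whose category is forced by construction.

    Counts per requested category follow ``category_proportions`` by
    largest-remainder apportionment (exact to within 1).  The pseudo-category
    "other" draws uniformly from the rarer protein-changing classes.  Raises
    :class:`CategoryPlacementError` naming the category when no valid site
    exists (e.g. splice alleles in an intron-less annotation).
    """
    rng = np.random.default_rng([config.seed, 1])
    counts = _apportion(config.category_proportions, config.n_alleles)
    finder = _SiteFinder(annotation, rng, config.flank_bp)
    gt = GroundTruth()
    alleles: list[Allele] = []

    has_introns = any(
        len(tx.exons) > 1 for tx in annotation.transcripts.values()
    )
    for cat in ("splice_donor", "splice_acceptor", "intronic"):
        if counts.get(cat, 0) > 0 and not has_introns:
            raise CategoryPlacementError(
                f"category {cat!r} requested but the annotation has no introns"
            )

    idx = 0
    for requested in sorted(counts):
        for _ in range(counts[requested]):
            category = requested
            if requested == "other":
                category = _OTHER_POOL[int(rng.integers(0, len(_OTHER_POOL)))]
            site = _find_site(finder, category)
            if site is None:
                raise CategoryPlacementError(
                    f"no valid site found for category {category!r} "
                    f"(requested as {requested!r})"
                )
            chrom, pos, ref, alt = site
            idx += 1
            aid = f"a{idx:05d}"
            alleles.append(
                Allele(id=aid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                       source="forward_genetics")
            )
            gt.allele_categories[aid] = category
            gt.allele_requested[aid] = requested
    return alleles, gt


def _find_site(finder: _SiteFinder, category: str):
    if category in ("synonymous", "missense", "stop_gained", "stop_lost", "start_lost"):
        return finder.cds_substitution(category)
    if category in ("splice_donor", "splice_acceptor", "five_prime_UTR",
                    "three_prime_UTR", "intronic"):
        return finder.region_substitution(category)
    if category in ("upstream", "downstream"):
        return finder.flank_substitution(category)
    if category == "intergenic":
        return finder.intergenic_substitution()
    if category in ("frameshift", "inframe_deletion", "inframe_insertion"):
        return finder.cds_indel(category)
    if category == "transcript_ablation":
        return finder.ablation_deletion()
    raise CategoryPlacementError(f"unsupported category {category!r}")


# ---------------------------------------------------------------------------
# Study / element tables
# ---------------------------------------------------------------------------

def generate_study_tables(
    config: SyntheticConfig,
) -> tuple[list[CuratedRecord], list[StudyRecord], GroundTruth]:
    """Generate a curated element table and a study table with known truth.

    Element distances are log-normal around ``distance_median`` (a stated
    simulation choice — real catalogues publish no generative model); effect
    directions are Bernoulli per region with ``down_probability``.  Study
    conclusions are derived from their sampled directions by the unanimity
    rule and stored as ground truth, as are exact per-technique totals and
    means of tested mutations.
    """
    rng = np.random.default_rng([config.seed, 2])
    gt = GroundTruth(distance_median=config.distance_median)

    region_pool = ("transcriptional_cis_regulatory", "five_prime_UTR", "three_prime_UTR")
    region_probs = (0.6, 0.15, 0.25)
    mu = math.log(config.distance_median)
    elements: list[CuratedRecord] = []
    for i in range(config.n_elements):
        region = region_pool[int(rng.choice(3, p=region_probs))]
        raw = int(round(float(rng.lognormal(mu, config.distance_sigma))))
        down = bool(rng.random() < config.down_probability[region])
        mechanism = ""
        if region == "three_prime_UTR" and down and rng.random() < 0.3:
            mechanism = "NMD"
        if region == "transcriptional_cis_regulatory":
            cls = "promoter" if raw > 100 else "core_promoter"
        elif region == "five_prime_UTR":
            cls = "five_prime_UTR"
        else:
            cls = "three_prime_UTR"
        eid = f"e{i + 1:04d}"
        elements.append(
            CuratedRecord(
                item_id=eid,
                region_class=cls,
                distance_raw=raw,
                distance_display=round_distance(raw),
                effect="down" if down else "up",
                severity=None,
                mechanism=mechanism,
                included=True,
            )
        )
        gt.element_distances[eid] = raw

    n_crispr = config.n_studies - config.n_reporter_studies - config.n_forward_studies
    if n_crispr < 0:
        raise ValueError("n_studies smaller than reporter + forward study counts")
    plan = (
        [("reporter", i) for i in range(config.n_reporter_studies)]
        + [("forward_genetics", i) for i in range(config.n_forward_studies)]
        + [("crispr", i) for i in range(n_crispr)]
    )
    studies: list[StudyRecord] = []
    per_tech: dict[str, list[int]] = {}
    for tech, i in plan:
        if tech == "reporter":
            n_mut = int(np.clip(round(float(rng.lognormal(math.log(18), 1.0))), 1, 200))
        elif tech == "forward_genetics":
            n_mut = int(rng.choice([1, 2], p=[0.6, 0.4]))
        else:
            n_mut = int(rng.integers(1, 11))
        regions = {region_pool[int(rng.choice(3, p=region_probs))]}
        if rng.random() < 0.15:
            regions.add(region_pool[int(rng.integers(0, 3))])
        # elements within one study mostly agree in direction: a second
        # element (30% of studies) repeats the first with probability 0.8
        directions = []
        for region in sorted(regions):
            p_down = config.down_probability[region]
            first = "down" if rng.random() < p_down else "up"
            directions.append(first)
            if n_mut > 1 and rng.random() < 0.3:
                if rng.random() < 0.8:
                    directions.append(first)
                else:
                    directions.append("down" if rng.random() < p_down else "up")
        acts = {"activating" if d == "down" else "repressive" for d in directions}
        conclusion = acts.pop() if len(acts) == 1 else "both"
        closest = furthest = None
        if tech == "reporter":
            d1 = int(round(float(rng.lognormal(mu, config.distance_sigma))))
            d2 = int(round(float(rng.lognormal(mu, config.distance_sigma))))
            closest, furthest = min(d1, d2), max(d1, d2)
        sid = f"{tech[:3]}{i + 1:03d}"
        studies.append(
            StudyRecord(
                study_id=sid,
                technique=tech,
                region_categories=frozenset(regions),
                n_mutations=n_mut,
                activity_conclusion=conclusion,
                closest_bp=closest,
                furthest_bp=furthest,
            )
        )
        gt.study_conclusions[sid] = conclusion
        gt.study_mutations[sid] = n_mut
        per_tech.setdefault(tech, []).append(n_mut)
    for tech, vals in per_tech.items():
        gt.technique_totals[tech] = int(sum(vals))
        gt.technique_means[tech] = sum(vals) / len(vals)
    return elements, studies, gt


# ---------------------------------------------------------------------------
# Reconstructed reference catalogue (synthetic stand-in)
# ---------------------------------------------------------------------------

def synthetic_catalogue_tables() -> tuple[list[CuratedRecord], list[StudyRecord], list[int]]:
    """Synthetic reconstruction of a published regulatory-allele catalogue.

    The real extended-data tables live behind a dataset DOI; this stand-in
    is built to carry the catalogue's reported marginal statistics exactly —
    reporter studies totalling 1,625 tested mutations with a 195-mutation
    maximum, endogenous studies totalling 87 with forward screens averaging
    1.4, 2 of 20 forward-genetics alleles in introns or downstream regions,
    and transcriptional element distances spanning 0 to 8,500 bp with a
    nearest-rank 95th percentile of 5,000 — so pipeline recoveries of those
    marginals can be checked without the download.  It is synthetic: row
    identities and every non-marginal value are invented.

    Returns (forward-genetics allele records, study records, element
    distances in bp).
    """
    # 50 reporter studies: descending plausible spread, max 195, total 1625
    reporter = [195, 150, 120, 100, 90, 80, 70, 65, 60, 55, 50, 45, 40, 38, 36,
                34, 32, 30, 28, 26, 24, 22, 20, 18, 16, 14, 12, 10, 9, 8,
                7, 6, 5, 5, 4, 4, 3, 3, 3, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1]
    reporter.append(1625 - sum(reporter))
    assert len(reporter) == 50 and max(reporter) == 195 and sum(reporter) == 1625
    # 35 forward screens averaging 1.4 (49 mutations) + 14 CRISPR studies (38)
    forward = [2] * 14 + [1] * 21
    crispr = [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 4, 4, 5, 7]
    assert sum(forward) + sum(crispr) == 87
    assert abs(sum(forward) / len(forward) - 1.4) < 1e-9

    studies: list[StudyRecord] = []
    for i, n in enumerate(reporter):
        studies.append(StudyRecord(f"rep{i + 1:03d}", "reporter",
                                   frozenset({"transcriptional_cis_regulatory"}), n))
    for i, n in enumerate(forward):
        studies.append(StudyRecord(f"fwd{i + 1:03d}", "forward_genetics",
                                   frozenset({"transcriptional_cis_regulatory"}), n))
    for i, n in enumerate(crispr):
        studies.append(StudyRecord(f"cri{i + 1:03d}", "crispr",
                                   frozenset({"transcriptional_cis_regulatory"}), n))

    # 40 transcriptional element distances: closest at 0 (intronic), nearest-rank
    # p95 = 5000, maximum 8500, median between 900 and 1500
    distances = [0, 0, 50, 100, 150, 200, 300, 350, 400, 500,
                 600, 700, 800, 850, 900, 950, 1000, 1050, 1100, 1200,
                 1300, 1400, 1500, 1600, 1800, 2000, 2200, 2500, 2800, 3000,
                 3200, 3500, 3800, 4000, 4300, 4600, 4800, 5000, 7000, 8500]
    assert len(distances) == 40 and distances[int(math.ceil(0.95 * 40)) - 1] == 5000

    # 20 forward-genetics non-coding alleles, 2 of them intronic/downstream
    regions = ["promoter"] * 12 + ["core_promoter"] * 3 + ["five_prime_UTR"] * 2 + \
              ["three_prime_UTR"] * 1 + ["intron", "downstream"]
    records = [
        CuratedRecord(item_id=f"fwd_allele{i + 1:02d}", region_class=r,
                      effect="down", included=True)
        for i, r in enumerate(regions)
    ]
    assert len(records) == 20
    return records, studies, distances
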