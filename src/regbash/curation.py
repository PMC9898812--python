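"""Curation of candidate non-coding alleles and regulatory elements.

The conservative exclusion rules mirror how a curated catalogue of
gene-regulatory alleles is assembled from the literature: anything that
changes protein sequence in any isoform (including via an ectopic splice
donor), any passenger mutation, and anything with insufficient functional
information is excluded, each with exactly one recorded reason.

Retained transcriptional elements are placed relative to their target
transcript's TSS: within ``core_promoter_bp`` (default 100 bp) of the TSS
they are core promoters; elements the source publication called "enhancer"
keep that label; the rest are plain promoters.  All three carry the umbrella
tag "transcriptional cis-regulatory".  Distances are reported both raw and
rounded the way such catalogues print them (to 50s below 1 kb, 100s up to
5 kb, 500s beyond).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GenomeAnnotation, Transcript
from .consequence import ConsequenceCall

__all__ = [
    "CuratedRecord",
    "StudyRecord",
    "REGION_CLASSES",
    "TRANSCRIPTIONAL_CLASSES",
    "EXCLUSION_REASONS",
    "apply_exclusion_rules",
    "assign_regulatory_class",
    "distance_to_tss",
    "round_distance",
    "infer_activity",
    "aggregate_study_activity",
    "curate_calls",
    "read_curation_table",
    "write_curated_tsv",
    "read_study_table",
    "write_study_table",
]

REGION_CLASSES = (
    "core_promoter",
    "promoter",
    "enhancer",
    "five_prime_UTR",
    "three_prime_UTR",
    "intron",
    "downstream",
    "unclassified",
)
TRANSCRIPTIONAL_CLASSES = frozenset({"core_promoter", "promoter", "enhancer"})
EXCLUSION_REASONS = (
    "protein_changing_any_isoform",
    "passenger",
    "insufficient_information",
)
DEFAULT_CORE_PROMOTER_BP = 100

# fine consequence categories whose region class passes through unchanged
_PASSTHROUGH = {
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "intronic": "intron",
    "downstream": "downstream",
}


@dataclass
class CuratedRecord:
    """An allele or reporter element after curation."""

    item_id: str
    region_class: str = "unclassified"
    distance_raw: int | None = None
    distance_display: int | None = None
    effect: str | None = None  # "up" | "down"
    severity: str | None = None  # "null" | "reduced" | None
    mechanism: str = ""
    source_label: str = ""
    target_gene: str | None = None
    included: bool = True
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.included != (self.exclusion_reason is None):
            raise ValueError(
                f"{self.item_id}: included must hold exactly when no exclusion reason is set"
            )
        if self.distance_raw is not None and self.distance_raw < 0:
            raise ValueError(f"{self.item_id}: distance_raw must be non-negative")

    @property
    def is_transcriptional(self) -> bool:
        return self.region_class in TRANSCRIPTIONAL_CLASSES


@dataclass
class StudyRecord:
    """One publication: technique, studied regions, throughput, conclusion."""

    study_id: str
    technique: str  # forward_genetics | crispr | reporter
    region_categories: frozenset[str] = frozenset()
    n_mutations: int = 1
    activity_conclusion: str | None = None  # activating | repressive | both | none
    closest_bp: int | None = None
    furthest_bp: int | None = None

    def __post_init__(self) -> None:
        if (
            self.closest_bp is not None
            and self.furthest_bp is not None
            and self.closest_bp > self.furthest_bp
        ):
            raise ValueError(f"{self.study_id}: closest_bp exceeds furthest_bp")


# ---------------------------------------------------------------------------
# Exclusion rules
# ---------------------------------------------------------------------------

_FLAG_COLUMNS = ("protein_change_reported", "passenger", "insufficient_info")


def _truthy(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    return bool(value) and not pd.isna(value)


def apply_exclusion_rules(
    calls: Sequence[ConsequenceCall],
    table: pd.DataFrame | None = None,
) -> tuple[list[CuratedRecord], list[CuratedRecord], list[str]]:
    """Partition calls into retained and excluded curated records.

    A call is excluded iff, in order: (a) its gene category is coding, or any
    isoform carries the ectopic-donor flag, or the curation table reports a
    protein change; (b) the table marks it a passenger mutation; (c) the
    table marks insufficient information.  The first matching reason is the
    only one recorded, so retained + excluded always partitions the input.

    Returns (retained, excluded, warnings); warnings list table rows that
    reference no call.
    """
    meta: Mapping[str, Mapping] = {}
    if table is not None:
        tbl = table.set_index("item_id") if "item_id" in table.columns else table
        meta = {str(k): row for k, row in tbl.to_dict(orient="index").items()}
    retained: list[CuratedRecord] = []
    excluded: list[CuratedRecord] = []
    seen_ids = set()
    for call in calls:
        seen_ids.add(call.allele_id)
        row = meta.get(call.allele_id, {})
        ectopic = any(tc.ectopic_donor_flag for tc in call.per_transcript)
        reason = None
        if (
            call.gene_category == "coding"
            or ectopic
            or _truthy(row.get("protein_change_reported"))
        ):
            reason = "protein_changing_any_isoform"
        elif _truthy(row.get("passenger")):
            reason = "passenger"
        elif _truthy(row.get("insufficient_info")):
            reason = "insufficient_information"
        rec = CuratedRecord(
            item_id=call.allele_id,
            effect=row.get("effect") or None,
            severity=(row.get("severity") or None),
            mechanism=str(row.get("mechanism") or ""),
            source_label=str(row.get("source_label") or ""),
            target_gene=row.get("target_gene") or call.gene_id,
            included=reason is None,
            exclusion_reason=reason,
        )
        (retained if rec.included else excluded).append(rec)
    warn = [
        f"curation table row {item} matches no consequence call"
        for item in meta
        if item not in seen_ids
    ]
    for w in warn:
        warnings.warn(w)
    return retained, excluded, warn


# ---------------------------------------------------------------------------
# Region class and TSS distance
# ---------------------------------------------------------------------------

def distance_to_tss(start: int, end: int, transcript: Transcript) -> tuple[int, int]:
    """Strand-aware distance from an element's nearest edge to the TSS.

    Anything at or downstream of the TSS — including elements inside introns
    or overlapping the transcript span — gets 0.  Upstream elements get the
    gap (in bp) between their TSS-proximal edge and the TSS.  Returns
    (raw, display-rounded).
    """
    tss = transcript.tss
    if transcript.strand == "+":
        raw = tss - end if end <= tss else 0
    else:
        raw = start - tss - 1 if start > tss else 0
    raw = max(raw, 0)
    return raw, round_distance(raw)


def round_distance(raw: int) -> int:
    """Round a TSS distance the way catalogues print estimates.

    Nearest 50 below 1 kb, nearest 100 between 1 and 5 kb, nearest 500
    beyond; ties round half-up.
    """
    if raw < 1000:
        unit = 50
    elif raw <= 5000:
        unit = 100
    else:
        unit = 500
    q = (Decimal(raw) / unit).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return int(q) * unit


def assign_regulatory_class(
    fine_category: str,
    distance_raw: int | None,
    source_label: str = "",
    core_promoter_bp: int = DEFAULT_CORE_PROMOTER_BP,
) -> str:
    """Region class of a retained element.

    UTR/intron/downstream consequence categories pass through; everything in
    transcriptional context follows the distance/label rule: core promoter
    within ``core_promoter_bp`` of the TSS, else the publication's
    "enhancer" label, else plain promoter.
    """
    if fine_category in _PASSTHROUGH:
        return _PASSTHROUGH[fine_category]
    if distance_raw is None:
        return "unclassified"
    if abs(distance_raw) <= core_promoter_bp:
        return "core_promoter"
    if source_label.strip().lower() == "enhancer":
        return "enhancer"
    return "promoter"


def curate_calls(
    calls: Sequence[ConsequenceCall],
    table: pd.DataFrame | None,
    annotation: GenomeAnnotation | None = None,
    core_promoter_bp: int = DEFAULT_CORE_PROMOTER_BP,
) -> tuple[list[CuratedRecord], list[CuratedRecord], list[str]]:
    """Full curation pass: exclusions, then distances and region classes.

    For each retained record the target transcript is the lexicographically
    first isoform of the target gene (gene hint from the table, else the
    called gene); records without an assignable target stay unclassified
    with a warning.
    """
    by_id = {c.allele_id: c for c in calls}
    retained, excluded, warns = apply_exclusion_rules(calls, table)
    for rec in retained:
        call = by_id[rec.item_id]
        tx = _target_transcript(rec, annotation)
        if tx is None:
            if call.fine_category in _PASSTHROUGH:
                rec.region_class = _PASSTHROUGH[call.fine_category]
            else:
                rec.region_class = "unclassified"
                warns.append(f"{rec.item_id}: no assignable target transcript")
            continue
        raw, display = distance_to_tss(call.start, max(call.end, call.start + 1), tx)
        rec.distance_raw, rec.distance_display = raw, display
        rec.region_class = assign_regulatory_class(
            call.fine_category, raw, rec.source_label, core_promoter_bp
        )
    return retained, excluded, warns


def _target_transcript(
    rec: CuratedRecord, annotation: GenomeAnnotation | None
) -> Transcript | None:
    if annotation is None or rec.target_gene is None:
        return None
    tids = annotation.genes.get(rec.target_gene)
    if not tids:
        return None
    return annotation.transcripts[tids[0]]


# ---------------------------------------------------------------------------
# Activity inference
# ---------------------------------------------------------------------------

def infer_activity(effect: str | None, severity: str | None = None) -> str | None:
    """Native-sequence activity implied by a mutation's expression effect.

    Downregulation (including complete loss — severity "null" — and partial
    loss — "reduced") implies the native sequence activates; upregulation
    implies it represses.  Unknown effect returns None with a warning.
    """
    if effect is None and severity in {"null", "reduced"}:
        effect = "down"
    if effect == "down":
        return "activating"
    if effect == "up":
        return "repressive"
    warnings.warn(f"unknown effect {effect!r}; record skipped")
    return None


def aggregate_study_activity(
    records: Iterable[CuratedRecord], nmd_filter: bool = False
) -> str:
    """Study-level conclusion: activating / repressive / both / none.

    With ``nmd_filter`` on, records whose mechanism is nonsense-mediated
    decay are dropped first — an ectopic NMD mutation downregulates without
    implying a native activating element.
    """
    acts: list[str] = []
    for rec in records:
        if nmd_filter and rec.mechanism.strip().upper() == "NMD":
            continue
        act = infer_activity(rec.effect, rec.severity)
        if act is not None:
            acts.append(act)
    if not acts:
        return "none"
    unique = set(acts)
    if unique == {"activating"}:
        return "activating"
    if unique == {"repressive"}:
        return "repressive"
    return "both"


# ---------------------------------------------------------------------------
# Table I/O (TSV with a versioned header line)
# ---------------------------------------------------------------------------

def read_curation_table(path: str | Path) -> pd.DataFrame:
    """Read a per-item curation table (flags, effect, severity, mechanism...)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if "item_id" not in df.columns:
        raise ValueError(f"{path}: curation table needs an item_id column")
    return df


def write_curated_tsv(
    records: Sequence[CuratedRecord], path: str | Path, kind: str = "curated_records"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"#regbash-table\tv1\t{kind}\n")
        fh.write(
            "item_id\tregion_class\tdistance_raw\tdistance_display\teffect\tseverity\t"
            "mechanism\tsource_label\ttarget_gene\tincluded\texclusion_reason\n"
        )
        for r in records:
            fh.write(
                "\t".join(
                    str(x) if x is not None else ""
                    for x in (
                        r.item_id, r.region_class, r.distance_raw, r.distance_display,
                        r.effect, r.severity, r.mechanism, r.source_label,
                        r.target_gene, int(r.included), r.exclusion_reason,
                    )
                )
                + "\n"
            )


def write_study_table(studies: Sequence[StudyRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#regbash-table\tv1\tstudies\n")
        fh.write(
            "study_id\ttechnique\tregion_categories\tn_mutations\tactivity_conclusion\t"
            "closest_bp\tfurthest_bp\n"
        )
        for s in studies:
            fh.write(
                "\t".join(
                    str(x) if x is not None else ""
                    for x in (
                        s.study_id, s.technique, ",".join(sorted(s.region_categories)),
                        s.n_mutations, s.activity_conclusion, s.closest_bp, s.furthest_bp,
                    )
                )
                + "\n"
            )


def read_study_table(path: str | Path) -> list[StudyRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    studies = []
    for _, row in df.iterrows():
        studies.append(
            StudyRecord(
                study_id=row["study_id"],
                technique=row["technique"],
                region_categories=frozenset(
                    c for c in row["region_categories"].split(",") if c
                ),
                n_mutations=int(row["n_mutations"]),
                activity_conclusion=row["activity_conclusion"] or None,
                closest_bp=int(row["closest_bp"]) if row["closest_bp"] else None,
                furthest_bp=int(row["furthest_bp"]) if row["furthest_bp"] else None,
            )
        )
    return studies
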