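"""Summary statistics over classified alleles and curated study catalogues.

Computes the headline numbers of a regulatory-allele survey: the category
breakdown of all alleles (what fraction is coding, splicing, non-coding),
the distribution of element-to-TSS distances (nearest-rank 95th percentile
and a bootstrap confidence interval of the median), per-region percentages
of inferred native activities, and per-technique experimental throughput.
Everything is emitted as a machine-readable JSON report plus per-figure TSV
tables with stable ordering, so two runs with the same seed are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel

from . import __version__
from .consequence import SEVERITY_ORDER, ConsequenceCall
from .curation import CuratedRecord, StudyRecord, aggregate_study_activity

__all__ = [
    "CategoryBreakdown",
    "DistanceSummary",
    "ThroughputSummary",
    "category_breakdown",
    "distance_stats",
    "activity_breakdown",
    "study_throughput",
    "build_report",
    "render_report",
    "AnalysisReport",
    "pct",
    "REGION_CATEGORIES",
    "TECHNIQUES",
]

GENE_CATEGORIES = (
    "coding",
    "splicing",
    "synonymous",
    "non_coding_regulatory",
    "intergenic_unassigned",
)
REGION_CATEGORIES = ("transcriptional_cis_regulatory", "five_prime_UTR", "three_prime_UTR")
TECHNIQUES = ("forward_genetics", "crispr", "reporter")
ACTIVITY_CONCLUSIONS = ("activating", "repressive", "both")


def pct(count: float, total: float, places: int = 1) -> float:
    """Percentage rounded half-up to ``places`` decimals (printed style)."""
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-places)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


def _mean_1dp(values: Sequence[int]) -> float:
    return float(
        (Decimal(sum(values)) / Decimal(len(values))).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


# ---------------------------------------------------------------------------
# Category breakdown
# ---------------------------------------------------------------------------

@dataclass
class CategoryBreakdown:
    """Counts per category; percentages are always recomputed from counts."""

    total: int
    gene_counts: dict[str, int] = field(default_factory=dict)
    fine_counts: dict[str, int] = field(default_factory=dict)

    @property
    def gene_pct(self) -> dict[str, float]:
        return {k: pct(v, self.total) for k, v in self.gene_counts.items()}

    @property
    def fine_pct(self) -> dict[str, float]:
        return {k: pct(v, self.total) for k, v in self.fine_counts.items()}

    @property
    def non_coding_count(self) -> int:
        """Non-coding in the catalogue sense: regulatory plus synonymous."""
        return self.gene_counts.get("non_coding_regulatory", 0) + self.gene_counts.get(
            "synonymous", 0
        )

    @property
    def non_coding_pct(self) -> float:
        return pct(self.non_coding_count, self.total)


def category_breakdown(calls: Sequence[ConsequenceCall]) -> CategoryBreakdown:
    """Count calls per gene-level and fine category.

    Every call contributes to exactly one gene category and one fine
    category, so both count families sum to the input size.  An empty input
    yields an empty breakdown rather than a division error.
    """
    bd = CategoryBreakdown(total=len(calls))
    for call in calls:
        bd.gene_counts[call.gene_category] = bd.gene_counts.get(call.gene_category, 0) + 1
        bd.fine_counts[call.fine_category] = bd.fine_counts.get(call.fine_category, 0) + 1
    return bd


# ---------------------------------------------------------------------------
# Distance distribution
# ---------------------------------------------------------------------------

@dataclass
class DistanceSummary:
    n: int
    min: float
    max: float
    percentile_95: float
    ci_low: float
    ci_high: float
    reliable: bool
    bootstrap_B: int
    seed: int


def distance_stats(
    distances: Sequence[float], B: int = 1000, seed: int = 0
) -> DistanceSummary:
    """Summarize element-to-TSS distances.

    The 95th percentile uses the nearest-rank method (the value at rank
    ceil(0.95 n) of the sorted sample).  The central interval is a
    percentile bootstrap (2.5, 97.5) of the sample median with ``B``
    resamples, deterministic per seed.  With fewer than 5 observations the
    point estimates are returned but the interval is marked unreliable.
    """
    arr = np.asarray(sorted(distances), dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("distance_stats requires at least one distance")
    if np.any(arr < 0):
        raise ValueError("distances must be non-negative")
    rank = int(np.ceil(0.95 * n))
    p95 = float(arr[rank - 1])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    medians = np.median(arr[idx], axis=1)
    lo, hi = np.percentile(medians, [2.5, 97.5])
    return DistanceSummary(
        n=n,
        min=float(arr[0]),
        max=float(arr[-1]),
        percentile_95=p95,
        ci_low=float(lo),
        ci_high=float(hi),
        reliable=n >= 5,
        bootstrap_B=B,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Activity and throughput
# ---------------------------------------------------------------------------

def activity_breakdown(
    studies: Sequence[StudyRecord],
    nmd_filter: bool = False,
    records_by_study: Mapping[str, Sequence[CuratedRecord]] | None = None,
) -> dict[str, dict[str, float | int]]:
    """Per-region percentages of study conclusions.

    A study spanning two region categories contributes to both denominators;
    studies whose conclusion is "none" (e.g. emptied by the NMD filter) drop
    out of the denominator.  When ``records_by_study`` is given, conclusions
    are recomputed from the underlying records under ``nmd_filter``.
    Regions with zero studies are omitted.
    """
    out: dict[str, dict[str, float | int]] = {}
    for region in REGION_CATEGORIES:
        tallies = {c: 0 for c in ACTIVITY_CONCLUSIONS}
        n = 0
        for s in studies:
            if region not in s.region_categories:
                continue
            conclusion = s.activity_conclusion
            if records_by_study is not None and s.study_id in records_by_study:
                conclusion = aggregate_study_activity(
                    records_by_study[s.study_id], nmd_filter=nmd_filter
                )
            if conclusion not in tallies:
                continue
            tallies[conclusion] += 1
            n += 1
        if n == 0:
            continue
        out[region] = {"n_studies": n}
        for c in ACTIVITY_CONCLUSIONS:
            out[region][c] = pct(tallies[c], n)
    return out


@dataclass
class ThroughputSummary:
    per_technique: dict[str, dict[str, float | int]] = field(default_factory=dict)


def study_throughput(studies: Sequence[StudyRecord]) -> ThroughputSummary:
    """Per-technique totals, per-study maxima and means of tested mutations."""
    out = ThroughputSummary()
    for tech in TECHNIQUES:
        counts = [s.n_mutations for s in studies if s.technique == tech]
        if not counts:
            continue
        out.per_technique[tech] = {
            "n_studies": len(counts),
            "total": int(sum(counts)),
            "max_per_study": int(max(counts)),
            "mean_per_study": _mean_1dp(counts),
        }
    return out


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

class CategoryBreakdownModel(BaseModel):
    total: int
    gene_category_counts: dict[str, int]
    gene_category_pct: dict[str, float]
    fine_category_counts: dict[str, int]
    fine_category_pct: dict[str, float]
    non_coding_count: int
    non_coding_pct: float


class DistanceModel(BaseModel):
    n: int
    min: float
    max: float
    percentile_95: float
    ci_low: float
    ci_high: float
    reliable: bool
    bootstrap_B: int
    seed: int


class RegionActivityModel(BaseModel):
    n_studies: int
    activating: float
    repressive: float
    both: float


class TechniqueThroughputModel(BaseModel):
    n_studies: int
    total: int
    max_per_study: int
    mean_per_study: float


class AnalysisReport(BaseModel):
    """Schema of the machine-readable report (also shipped as JSON Schema)."""

    version: str
    seed: int
    inputs: dict[str, int]
    categories: CategoryBreakdownModel | None = None
    distances: DistanceModel | None = None
    activity: dict[str, RegionActivityModel | None] = {}
    throughput: dict[str, TechniqueThroughputModel | None] = {}


def build_report(
    breakdown: CategoryBreakdown | None,
    distance_summary: DistanceSummary | None,
    activity: Mapping[str, Mapping[str, float | int]] | None,
    throughput: ThroughputSummary | None,
    seed: int,
    inputs: Mapping[str, int],
) -> AnalysisReport:
    """Assemble the validated report object.

    Region and technique keys are always present (null when empty) so
    downstream consumers never have to distinguish "absent" from "empty".
    """
    cats = None
    if breakdown is not None:
        cats = CategoryBreakdownModel(
            total=breakdown.total,
            gene_category_counts=dict(sorted(breakdown.gene_counts.items())),
            gene_category_pct=dict(sorted(breakdown.gene_pct.items())),
            fine_category_counts=dict(sorted(breakdown.fine_counts.items())),
            fine_category_pct=dict(sorted(breakdown.fine_pct.items())),
            non_coding_count=breakdown.non_coding_count,
            non_coding_pct=breakdown.non_coding_pct,
        )
    dist = None
    if distance_summary is not None:
        dist = DistanceModel(**distance_summary.__dict__)
    act: dict[str, RegionActivityModel | None] = {}
    for region in REGION_CATEGORIES:
        row = (activity or {}).get(region)
        act[region] = RegionActivityModel(**row) if row else None
    thr: dict[str, TechniqueThroughputModel | None] = {}
    for tech in TECHNIQUES:
        row = (throughput.per_technique if throughput else {}).get(tech)
        thr[tech] = TechniqueThroughputModel(**row) if row else None
    return AnalysisReport(
        version=__version__,
        seed=seed,
        inputs=dict(sorted(inputs.items())),
        categories=cats,
        distances=dist,
        activity=act,
        throughput=thr,
    )


def render_report(report: AnalysisReport, out_path: str | Path) -> list[Path]:
    """Write the JSON report (stable key order) and per-figure TSV tables.

    Tables land next to the JSON: categories.tsv, distances.tsv,
    activity.tsv, throughput.tsv.  Returns all written paths.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(
        json.dumps(report.model_dump(), indent=2, sort_keys=True) + "\n"
    )
    written = [out_path]
    d = out_path.parent

    p = d / "categories.tsv"
    with open(p, "w") as fh:
        fh.write("#regbash-table\tv1\tcategories\n")
        fh.write("level\tcategory\tcount\tpercent\n")
        if report.categories:
            c = report.categories
            for k in sorted(c.gene_category_counts):
                fh.write(f"gene\t{k}\t{c.gene_category_counts[k]}\t{c.gene_category_pct[k]}\n")
            for k in sorted(c.fine_category_counts, key=lambda x: SEVERITY_ORDER.index(x)):
                fh.write(f"fine\t{k}\t{c.fine_category_counts[k]}\t{c.fine_category_pct[k]}\n")
    written.append(p)

    p = d / "distances.tsv"
    with open(p, "w") as fh:
        fh.write("#regbash-table\tv1\tdistances\n")
        fh.write("n\tmin\tmax\tpercentile_95\tci_low\tci_high\treliable\n")
        if report.distances:
            x = report.distances
            fh.write(
                f"{x.n}\t{x.min}\t{x.max}\t{x.percentile_95}\t{x.ci_low}\t{x.ci_high}\t"
                f"{int(x.reliable)}\n"
            )
    written.append(p)

    p = d / "activity.tsv"
    with open(p, "w") as fh:
        fh.write("#regbash-table\tv1\tactivity\n")
        fh.write("region\tn_studies\tactivating\trepressive\tboth\n")
        for region in REGION_CATEGORIES:
            row = report.activity.get(region)
            if row:
                fh.write(
                    f"{region}\t{row.n_studies}\t{row.activating}\t{row.repressive}\t{row.both}\n"
                )
            else:
                fh.write(f"{region}\t0\t\t\t\n")
    written.append(p)

    p = d / "throughput.tsv"
    with open(p, "w") as fh:
        fh.write("#regbash-table\tv1\tthroughput\n")
        fh.write("technique\tn_studies\ttotal\tmax_per_study\tmean_per_study\n")
        for tech in TECHNIQUES:
            row = report.throughput.get(tech)
            if row:
                fh.write(
                    f"{tech}\t{row.n_studies}\t{row.total}\t{row.max_per_study}\t"
                    f"{row.mean_per_study}\n"
                )
            else:
                fh.write(f"{tech}\t0\t\t\t\n")
    written.append(p)
    return written
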