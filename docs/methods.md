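# Methods

## Annotation model

GFF3 (1-based, closed) is read through gffutils into a transcript-centric
model; all internal arithmetic is 0-based, half-open, and BED output is
0-based half-open. A transcript is an ordered list of exons plus optional
CDS segments; UTRs are derived as exon ∖ CDS split by side, introns as the
gaps between consecutive exons, and splice donor/acceptor sites as the first
and last two intronic bases on the transcript strand. The donor/acceptor
width of 2 bp matches the canonical GT/AG dinucleotides; variants deeper in
the intron are classified `intronic` (an input table may annotate them
`splice_unclear`, which is treated as a pass-through label, not computed —
there is no computable definition for it). Each transcript also gets
upstream/downstream flanks of `flank_bp` (default 5,000 bp, the span that
contains the large majority of known regulatory elements; configurable).

### Overlap resolution

`resolve_overlaps` reduces any set of typed intervals to a disjoint set in
which every base carries the highest-precedence kind that covered it. The
default precedence — CDS > splice donor > splice acceptor > 5'UTR > 3'UTR >
intron > upstream flank > downstream flank — encodes a conservative reading:
when in doubt, a base is the kind under which a mutation there would *not*
count as regulatory. The exact order below CDS is a package decision (the
convention in curated catalogues is only illustrated by the 3'UTR-truncated-
by-CDS case) and is exposed as a parameter. The implementation is a sweep
over elementary segments with attribution ties broken by transcript id; its
oracle is brute-force per-base labelling, tested on random fixtures.

## Consequence classification

Per transcript: a deletion covering the whole span is `transcript_ablation`;
CDS substitutions are resolved through the standard nuclear codon table into
`start_lost` (annotated first codon only — downstream in-frame ATGs are not
rescued), `stop_lost`, `stop_gained`, `missense`, `synonymous`; CDS indels
are `frameshift` when the net length change is not a multiple of 3, else
`inframe_deletion`/`inframe_insertion`; everything else falls through
splice-site, UTR, intron and flank interval lookup to `intergenic`.

A synonymous substitution is additionally screened for ectopic splice-donor
creation: the edit window (one base of reference context each side, coding
orientation) is scanned for a GT at an offset where the reference has none.
This is a minimal motif test, not a splice-strength model — the phenomenon
is what matters for curation, not a score.

Gene-level aggregation takes the most severe per-isoform category
(severity order: ablation > frameshift > stop gained > stop lost > start
lost > in-frame indels > missense > splice donor > acceptor > unclear >
synonymous > 5'UTR > 3'UTR > intron > upstream > downstream > intergenic;
ties by transcript id) and maps it to one of five gene categories: coding,
splicing, synonymous, non_coding_regulatory, intergenic_unassigned. A
synonymous winner with an ectopic-donor flag on any isoform is reclassified
coding. By default the driver emits one call per allele — the most severe
across *all* genes it touches — so category counts partition the allele set;
`per_gene=True` reports an allele once per overlapped gene instead.

## Curation

Exclusion reasons apply in fixed order so each excluded record has exactly
one: (a) protein-changing in any isoform (computed, ectopic-donor flag, or
reported by the source publication), (b) passenger mutation, (c)
insufficient information. Passenger and information status are inputs, as
they are judgement calls made from the literature, not computable.

Region classes: within `core_promoter_bp` of the TSS (default 100 bp, read
as a symmetric window |d| ≤ 100; the directional reading is ambiguous and
the parameter is exposed) an element is a core promoter; otherwise a
source-labelled "enhancer" keeps that label; remaining transcriptional
elements are promoters. UTR/intron/downstream consequence categories pass
through as their own region classes. Core promoters, promoters and enhancers
together form the umbrella class "transcriptional cis-regulatory".

Distances to the TSS are strand-aware gaps from the element edge nearest the
TSS; anything at or downstream of the TSS (intragenic elements included) is
0, reconciling distance-to-TSS reporting with intronic elements "at 0 bp".
Display rounding mimics how such catalogues print estimates — nearest 50
below 1 kb, nearest 100 between 1 and 5 kb, nearest 500 beyond, half-up —
and raw distances are always retained (display is within 250 bp of raw).

Activity: effect "down" (including severity "null" and "reduced", which both
code as down) implies the native sequence activates; "up" implies it
represses. A study concludes "activating"/"repressive" on unanimity, "both"
otherwise; an optional NMD filter first removes records whose mechanism is
nonsense-mediated decay, since ectopic NMD downregulation does not indicate
a native activating element. The up↔down involution flips every conclusion
and fixes "both" (property-tested).

## Summary statistics

Percentages are computed from counts, half-up to one decimal (printed
style); families therefore sum to 100 within 0.1 per member. The distance
summary uses the nearest-rank 95th percentile (rank ⌈0.95·n⌉) and a
percentile bootstrap (2.5, 97.5) of the sample median with B resamples
(B = 1,000 in tests, 10,000 default in the CLI), deterministic per seed;
below n = 5 the interval is flagged unreliable. The choice of the median's
bootstrap CI as the "central interval" is a package decision — a density
mode interval would be an alternative reading and neither is asserted as
canonical. The JSON report is validated by a pydantic model (shipped also as
JSON Schema in `report_schema.json`); region and technique keys are always
present, null when empty, and key order is stable so equal inputs give
byte-identical files.

## Synthetic data

The generator emulates the relevant structure of a compact annotated
genome, not realistic sequence composition (no operons, trans-splicing or
ncRNA genes; base composition is uniform):

- Genes: 14 by default across two 150-kb chromosomes, ~50% minus strand,
  5'UTR 60–150 bp, 3'UTR 80–200 bp, 90–150 internal codons, 2–3 introns of
  45–120 bp with GT…AG ends, intergenic gaps of 10.5–13 kb (wider than two
  flanks, so upstream/downstream/intergenic placements exist
  unambiguously). Every CDS is ATG + non-stop codons + stop, so all
  fixtures translate cleanly by construction.
- Isoforms (1–2 per gene) share exons and differ in translation start via a
  downstream in-frame ATG, creating bases that are 5'UTR in one isoform and
  CDS in another — the exact case the any-isoform exclusion rule targets.
  An optional overlapping-genes mode pulls every second gene back so its
  5' head (including CDS start) lies inside the previous gene's 3'UTR,
  exercising overlap resolution.
- Alleles: requested category proportions are realized by largest-remainder
  apportionment; each allele's site is searched so that its category is
  forced by construction (e.g. a missense site is a non-synonymous,
  non-stop substitution in the CDS shared by all isoforms, clear of start
  codons, and no foreign gene's feature could impose a more severe
  category there). The default mixture mirrors a forward-genetics allele
  catalogue: 47.4% missense, 27.7% stop gained, 5.3% other protein-changing,
  10.8%/4.6% splice acceptor/donor, and a small regulatory remainder. The
  gene/intron counts above were chosen so every category in this mixture has
  forced sites with margin at n = 1,000 across seeds. Deletions and
  insertions are placed so left-alignment cannot move them across feature
  boundaries (in-frame events additionally forbid any shift, so the protein
  oracle sees exactly one residue gained or lost).
- Study tables: element distances are log-normal around a median of
  1,200 bp (σ = 0.8 in log space) — a stated simulation choice, since real
  catalogues publish no generative model; effect directions are Bernoulli
  per region (P(down) = 0.8 for transcriptional and 5'UTR elements, 0.25
  for 3'UTR), with a second element per study agreeing with the first 80% of
  the time; per-study mutation counts are log-normal for reporter studies
  and small integers (mean 1.4) for forward screens. Ground truth stores
  exact realized totals/means and the generating median.
- Determinism: all randomness flows from numpy Generators seeded from the
  single config seed (separate streams for genome, alleles, tables);
  identical config + seed gives byte-identical FASTA/GFF3/TSV.

A separate, fully deterministic *reconstructed catalogue*
(`synthetic_catalogue_tables`) carries the marginal statistics of a
published study catalogue (reporter total 1,625 / max 195, endogenous total
87, forward mean 1.4, distance range 0–8,500 bp with nearest-rank p95 at
5,000, 2/20 forward alleles intronic/downstream) with invented row
identities, so recovery of those marginals is testable offline.

What passing tests show — and do not. Perfect label recovery on forced
sites demonstrates the classifier implements its rules exactly; it does not
certify behaviour on real-genome pathologies the generator avoids
(overlapping isoform frames, non-canonical splice sites, complex
multi-nucleotide variants). Parameter-recovery results show the summary
machinery is unbiased under the stated generative model, not that the model
matches real catalogues.

## Numerical and degenerate-input choices

- Coordinates: 0-based half-open internally; GFF3 1-based closed; BED
  0-based half-open. Insertions are zero-length internally and exported as
  the single base before which they occur.
- Indels are left-aligned on load (the conventional normalization; the
  choice is invisible to category assignment by construction in fixtures).
- Ref-mismatch allele rows are rejected per row with line numbers; loading
  continues. Exact duplicate rows collapse with a warning count. Alleles on
  unannotated chromosomes classify as intergenic with a warning, not an
  error.
- Empty inputs: empty allele files and empty call lists are valid (empty
  outputs, no division errors); an empty distance list is an error.
- Apportionment ties in the allele mixture and severity ties across
  isoforms are broken deterministically (largest fractional part then name;
  lexicographic transcript id).

## Known limitations

Start-codon rescue, NMD prediction, splice-strength scoring and
protein-domain context are out of scope. Multi-allelic and structural
variants are not modelled. The curation stage automates the *rules*, not
the literature judgements they consume (passenger status, mechanism,
enhancer labels are inputs). GTF and ncRNA feature kinds are unsupported.
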