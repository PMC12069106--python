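# Methods

## Chemical identity and matching

All cross-source comparisons run on three machine identifiers: CAS Registry
Number, InChIKey, and SMILES. A pair of records matches when *any* shared
identifier kind agrees exactly after normalization (union semantics), and the
reported `matched_on` kind is the first agreeing kind in precedence order
CAS > InChIKey > SMILES. Union semantics were chosen because the source lists
are heterogeneous — many rows carry only a CAS number, others only structural
identifiers — and requiring agreement on every shared kind would silently drop
matches wherever one source carries a stale or differently-derived key.
Pairs whose remaining shared kinds disagree still match but are emitted as
warnings so curators can audit the conflicts.

CAS normalization strips whitespace and leading zeros in the first block,
inserts hyphens for all-digit input, and computes the registry check digit
(with positions numbered 1, 2, 3, … from the rightmost non-check digit, the
weighted digit sum mod 10 must equal the final digit). Numbers that fail the
check are flagged but **retained and matchable**: registry numbers in real
inventories must be reproducible verbatim, and dropping them would silently
shrink the matched universe. Both behaviours (flagging, retention) are
auditable through the parse result, so users preferring checksum-filtered
comparisons can filter on `checksum_valid` themselves.

SMILES are compared as exact trimmed strings by default; RDKit
canonicalization is available as an explicit opt-in (`smiles_mode=
"canonical"`), since structure-level matching changes the semantics of the
comparison and is not needed when both sides derive from the same curated
collections. Chemical names are never used in automated matching — only in a
separate lookup helper — because name matching at inventory scale requires
human judgement. Mixtures (e.g. chlorinated paraffins) carry CAS only; the
registry never requires structural identifiers.

## Step 1: biomonitoring programs and metabolome/exposome databases

Biomonitoring analytes marked as metabolites of a specific parent compound
are expanded: for each such row an additional row carrying the parent CAS,
same program, and same status is emitted, so an FCC is identified regardless
of whether the program measured the parent or the metabolite. Expansion
applies only to biomonitoring sources; the metabolome/exposome databases do
not systematically report metabolite–parent links, and no metabolite
prediction is attempted.

Per-FCC status resolution is a pure set computation: the monitored programs
are those with any matching analyte, the detected programs those with any
matching analyte of status *detected*, and database membership is recorded
per metabolome source. Any single detection dominates non-detection
elsewhere. A metabolome/exposome listing alone counts as evidence of
presence (*detected*), including all three HMDB metabolite statuses
("detected and quantified", "detected but not quantified", "expected but not
quantified"); per-database provenance is retained so stricter users can
filter, e.g. drop "expected" HMDB rows. Consequently *monitored but not
detected* requires a non-detection in some program **and** absence from
every metabolome/exposome database.

## Step 2: prioritization and the systematic evidence map

Candidates are the FCCs absent from every step-1 source (never monitored,
never listed). They are prioritized when the FCM migration/extraction
database reports their detection in ≥ 5 entries (entries with
`detected=false` — targeted in FCMs but never found — do not count).
The threshold is inclusive and configurable; raising it can only shrink the
prioritized set.

Literature inputs are post-screening extraction records; search and
eligibility screening are human workflows upstream of this package. One
positive record makes an FCC *detected*; only-negative records yield
*monitored but not detected*; no records yield *no evidence*. FCCs whose
searches found no studies and FCCs whose studies were all ineligible both
arrive without records and therefore both map to *no evidence*; the study
count is retained for finer distinctions. A study contributes once to an
FCC's study count regardless of how many sample types it reports;
sample-type aggregation is record-level, with multi-membership (an FCC
detected in urine and blood counts under both). Detections reported only via
an unspecific shared metabolite count as evidence but carry a flag.

## Hazard tiering

GHS classification records from the two inventories (ECHA C&L, Japanese GHS)
are pooled with equal weight; no source precedence is applied, and the
assigned tier is the precedence maximum over records:

| tier | trigger |
|---|---|
| high | CMR category 1A/1B, or STOT RE category 1 |
| medium | CMR or STOT RE category 2 |
| other_concern | any other classification (e.g. aquatic toxicity, skin sensitization) |
| not_classified | data in ≥ 1 hazard category, no classification |
| no_hazard_data | no records at all |

Max-pooling makes the assignment order-invariant and monotone: adding a
record never lowers a tier. Chemicals whose two inventories would disagree
on their own are flagged. Endocrine disruption, persistence,
bioaccumulation, and mobility are outside the tiering; records for them
still count as "data exist" for the not_classified/no_hazard_data
distinction. STOT single-exposure and all other non-CMR/STOT-RE classes map
to the `other` hazard class. Reports merge other_concern and not_classified
into one band; both are kept distinct internally.

Two subsets are hazard-mapped by default: the FCCs monitored in ≥ 1
biomonitoring program that also have ≥ 1 FCM detection entry (the
"biomonitored-and-in-FCM" subset, computed as that intersection since no
formulaic definition exists upstream; an explicit subset file can override
it), and the prioritized step-2 FCCs.

## Consolidation and reporting

One record per registry FCC: *detected* if detected in step 1 or step 2;
*monitored but not detected* if monitored anywhere and never detected;
*no evidence* otherwise. The three statuses partition the universe on every
run — this conservation law is asserted property-based in the tests. A
step-2 status for an FCC with any step-1 presence is a hard consistency
error. Headline percentages round to the nearest integer. Group labels are
curated inputs (expert/structure-based grouping is out of scope); group
summaries report the FCM-evidence weight (summed detection entries of
members) and a human-evidence weight — summed monitoring-program counts for
the biomonitored subset, distinct studies touching ≥ 1 member for the
prioritized subset. Sankey exports cross evidence status with the merged
tier bands; flows conserve subset size.

## Synthetic universes

The upstream sources are proprietary or living databases, so tests and the
acceptance script run on synthetic universes. A `UniverseSpec` fixes the
marginal counts and overlaps; generation is **quota-constructive** —
memberships are assigned to satisfy every count exactly rather than sampled
from probabilities — because the verification surface is exact count
recovery. Infeasible specs (e.g. an overlap larger than a margin, or an
inventory partition inconsistent with the implied detected count) fail with
an explanatory error before any file is written. Free attributes (program
assignments, FCM materials, study layouts, which FCCs are routed through
metabolite links) come from a single seeded RNG, so identical specs yield
byte-identical bundles and different seeds move only the free attributes,
never the quotas.

Defaults chosen for the generator, with rationale:

* `paper_marginals()` encodes the published marginal structure: 14,402 known
  FCCs; 194 biomonitoring-detected plus 71 monitored-only (13 monitored in
  all five programs, 8 detected in all five); 3528 metabolome-listed with a
  184-FCC overlap with the biomonitoring detections and 61 of the 71
  non-detections listed; HMDB statuses 367/1072/772; detected-set inventory
  partition 1883/863/792; 175 prioritized FCCs at threshold 5, 68 with
  studies, 5 all-negative; per-sample-type detection counts (urine 28, serum
  20, blood 13, plasma 12, breast milk 13, umbilical cord 18, placenta 6);
  tier quotas 100/44/77/14 over the 235-FCC biomonitored subset and
  5/13/98/59 over the prioritized set.
* 10% of biomonitoring analytes are routed through metabolite rows with
  parent links (`metabolite_link_fraction=0.10`), so metabolite expansion is
  always on the matched path; the real programs report metabolites for a
  minority of analytes, and any nonzero fraction exercises the mechanism
  without changing counts.
* Synthetic CAS numbers come from a reserved high block (first block
  9,000,000+; metabolites 8,500,000+) so they cannot collide with real
  registry numbers, and all carry valid check digits.
* 40 below-threshold candidates (1–4 detection entries) are included in the
  preset so the prioritization threshold is exercised on both sides.
* `hazard_no_data_no_evidence` places a chosen number of the prioritized
  set's no-hazard-data FCCs on members without any step-2 study (49 in the
  preset), reproducing the published data-gap intersection; left unset, the
  no-data quota fills from the never-studied tail.
* One prioritized chemical receives 99 detection entries, mirroring the
  heavy tail of FCM detection counts; one literature study applies both
  targeted and non-targeted methods.

What the generator does **not** emulate: realistic structures, names, or
concentrations; name variants and identifier errors across sources (every
synthetic identifier is internally consistent, so matching exercises the
logic, not fuzzy reconciliation); per-program analyte panel sizes; and
bibliographic structure (studies are per-FCC). Passing tests therefore show
that the set algebra, classification rules, and accounting are correct under
the stated marginal structure — not that real-world identifier curation
issues are handled beyond the explicit mechanisms above (invalid-checksum
retention, conflict warnings, manual CAS patches).

## Numerical and degenerate-input choices

All quantities are integer counts; there is no floating-point tolerance
anywhere except the headline percentage (nearest-integer rounding). Ties in
prioritization order break by chem_id; output files sort deterministically.
Empty inputs are legal everywhere (empty subsets tally to zero, an empty
record set writes a header-only file). Strict loading (pipeline default)
fails on any invalid row; lenient mode drops and counts them, and load
reports always conserve read = kept + rejected.

## Problem sizes

The full preset universe (14,402 chemicals, ~4,000 source rows) generates
and runs in well under a second on one core; property-based suites use
universes of ≤ 50 chemicals with brute-force nested-loop oracles, and the
checksum validator is cross-checked against an independent digit-loop oracle
on 1,000 random strings.

## Known limitations

* Matching is exact-key; near-miss identifiers (typos, salt forms, tautomer
  variants) do not match unless canonical-SMILES mode is enabled and both
  sides parse.
* The biomonitored-and-in-FCM subset definition is a package design choice
  (intersection rule above); alternative curated subsets must be supplied
  explicitly.
* Step-2 "no evidence" conflates "no studies found" with "no eligible
  studies", as the inputs arrive post-screening.
* Hazard tiering reflects the supplied classification snapshots; chemicals
  lacking data may be reclassified as inventories grow.
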