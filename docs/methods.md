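# Methods

## Scope and model

`cnvbench` evaluates germline CNV call sets (deletions and duplications
from short-read WGS) for clinical gene-panel use.  The clinical question
is coding-sequence disruption, so the comparison unit is not the event
pair but the **padded coding exon**: a canonical transcript's coding
exon extended by `pad = 15` bp of intron on each side (clipped at contig
boundaries) so that events clipping a splice junction still count.  A
query call and a truth event *match* when they overlap (≥ 1 bp) at least
one common padded exon and have the same dosage direction (DEL with DEL,
DUP with DUP).  No reciprocal-overlap or breakpoint condition links the
call to the truth event itself: a call with a wildly overextended
breakpoint still matches through the shared exon, and only becomes a
false positive by reaching an exon the truth set does not touch.
Copy-number magnitude and genotype are not compared.

Counting follows the GA4GH convention of separate truth-side and
query-side tallies at event granularity.  Each query contributes exactly
one TP or FP regardless of how many exons it overlaps or how many truth
events it matches; each truth event contributes one detected/FN
regardless of how many queries found it.  This is the multi-exon
double-counting adjustment: exon-level counting would let one large
event dominate a stratum.  The adjustment is isolated in
`adjust_multi_exon`, so an exon-level variant could be swapped in.

Queries overlapping no in-scope exon are **ignored**, not counted as
FP.  In a panel evaluation (`restrict_to` regions or a `--panel` gene
list) the rest of the genome is uncharacterized, so off-panel calls are
unknowable rather than wrong; counting them as FP would make panel
precision meaningless.  Genome-wide evaluations simply pass all
canonical (plus synthetic) transcripts, in which case "in scope" means
"any coding exon".  Truth events overlapping no exon are likewise
excluded from the sensitivity denominator; a caller cannot be penalized
for missing an event the scoring universe cannot see.  Empty
denominators yield null rates (never 0): a stratum with no DUP truth
events has undefined DUP sensitivity, not zero.

### Stratification

Default strata: event type; event length in the bins 0.5–1, 1–5, 1–10,
≥5 and >10 kb; and exons spanned in the bins 1, 2–5 and >5.  The length
binnings deliberately overlap (they serve different reporting
granularities), so each named bin is evaluated independently rather
than as a partition; ranged bins are half-open (`lo ≤ x < hi`), ">N"
bins strict.  An event's exon count is the number of distinct in-scope
padded exons the event itself overlaps; truth events are stratified by
their own properties and queries by theirs, which means a small query
confirming a large truth event lands in different bins on each side.
Events outside every configured length bin still count in ALL.

## Truth-set preparation

SV truth sets frequently represent tandem duplications as
sequence-resolved insertions, which a dosage-direction benchmark cannot
use.  `verify_duplication` tests whether the inserted sequence is a
copy of the adjacent reference: for each flank (a reference window of
the insertion's length `L` ending at the insertion point, or starting
at it) and each integer offset in `[-2, +2]`, the ungapped
(Hamming-style) identity over the aligned window is computed; the best
(identity, offset, flank) wins, with ties broken deterministically
(higher identity, then smaller |offset|, right flank first).  The
insertion is accepted as a duplication iff the best identity is
≥ 0.95.  The emitted DUP spans the *matched reference segment* — the
duplicated footprint is what downstream exon overlap needs — not the
single-base insertion point.  Rejected insertions (including N-only
sequences and windows that would run off the contig) are excluded from
the truth set, each with a recorded reason in the audit table.

The 2 bp "slop" is realized as the positional offset scan, not as a
gapped alignment: the tolerance being modelled is imprecision in the
annotated repeat boundary, and a full aligner would accept partial or
gapped matches that the identity threshold is meant to reject.  A
gapped-alignment mode is a possible extension but changes the meaning
of the 95% threshold.

Both flanks are always tested because a tandem duplication may be
annotated at either copy's boundary.  After conversion, the truth set is
restricted to the evaluated size window, 500 bp to 10 Mb inclusive at
both ends.

## Synthetic gene spiking

Sparse truth sets yield few scoreable exon overlaps.  The spiker plants
translated copies of template gene structures (all inter-exon distances
preserved, strand copied; no sequence is synthesized — placement is
coordinate-only):

- **General mode** scans each contig left to right and places templates
  (round-robin from a seed-shuffled cycle) so that each synthetic gene
  span lies wholly inside a high-confidence region, overlaps no real
  gene span (conservatively, first-exon-start to last-exon-end), and
  starts ≥ `min_gap = 100 kb` after the previous synthetic gene's end
  on that contig.  The greedy deterministic scan makes placement
  reproducible: same seed, same inputs, identical output.
- **On-top-of mode** anchors a template over each truth event of a
  chosen type (typically duplications, the sparse class) so that at
  least one exon overlaps the event span, under the same containment
  and real-gene constraints; the min-gap rule cannot apply because the
  anchor is dictated by the event.

An unreachable target count produces a shortfall report, not an error.
`audit_spiked_genes` re-checks every constraint by linear scan,
independent of the placement data structures, and is run by tests and
the `spike-genes` command on every output.

## Artifact filtering and blacklist discovery

High-sensitivity callers produce systematic false positives that
post-filters can remove without costing sensitivity.  Five rules, all
evaluated for every call (kept ⇔ no rule fails; the fixed evaluation
order never affects the kept set because all failures are recorded):

| rule | condition | default |
|---|---|---|
| SIZE_MIN | length < min_len | 500 bp |
| SIZE_MAX | length > max_len | 10 Mb |
| JUNCTION_LONG | junction-only evidence (SVCLAIM=J) and length > cap | 1 Mb |
| GAP_OVERLAP | ≥ 1 bp overlap with an assembly-gap region | gap-track BED |
| RECURRENT_ARTIFACT | matches a same-type catalogued artifact | recip ≥ 0.90 |

Junction-only calls above ~1 Mb are overwhelmingly artifacts because
true events of that size virtually always carry depth support; calls
with no evidence annotation are treated as UNKNOWN and never hit this
rule.  Artifact matching is svtype-aware (a DEL artifact never filters
a DUP) because dosage direction is the package's universal matching
currency.

The recurrent-artifact rule has two modes.  The default evaluates
reciprocal overlap `min(ov/len(call), ov/len(artifact)) ≥ 0.90`
directly.  The **two-BED mode** reproduces the containment surrogate
used by BED-only filter engines: the call must contain the cluster's
minimum interval (members' intersection) and be contained by its
maximum interval (members' union).  The surrogate is slightly stricter
at the boundary — a call at exactly 0.90 reciprocal overlap against a
point cluster is dropped in direct mode but kept by containment — which
is why both modes exist and the tests pin the difference.

`build_blacklist` discovers the artifact catalogue from ≥ 2 samples'
call sets: same-type calls across all samples are single-linkage
clustered under the reciprocal-overlap ≥ 0.90 relation (members sorted
canonically first, so the result is invariant to sample ordering), and
clusters present in ≥ `min_recurrence = 2` distinct samples become
artifact regions.  The representative interval takes median endpoints;
min/max intervals are the intersection and union.  A degenerate chain
cluster whose members share no common core falls back to the
representative for the min interval so the two-BED test stays defined.
Single-linkage was chosen because artifact clusters in practice are
tight recurrences of the same breakpoints; at 0.90 the relation is
nearly transitive and chaining is not a practical concern.

## Coordinates and formats

Internally everything is 0-based half-open; "1 bp overlap" means the
intervals share at least one base (half-open adjacency is not overlap).
BED passes through unchanged; VCF POS is converted by −1 on read and +1
on write, so a DEL at POS=1001 with END=2000 is `[1000, 2000)`, length
1000.  One htslib quirk required an explicit contract: for symbolic
records carrying SVLEN, htslib ≥ 1.16 recomputes the span with a
padding-base convention, silently shifting the end by +1 and overriding
INFO/END.  The reader therefore treats SVLEN as authoritative when
present (`end = start + |SVLEN|`) and uses END otherwise; the writer
emits SVTYPE and END without SVLEN, which round-trips exactly.  Contig
names are matched as exact strings, with an optional flag to strip
`chr` prefixes since GRCh37 resources mix the two conventions.

Gene models load from BED12 (blocks = coding exons) or GFF3 (CDS
features grouped by transcript Parent; minus-strand exons stored in
ascending coordinate order).  Canonical-transcript selection is the
input file's responsibility.  Overlapping exons within one model are
merged with a warning; zero-exon transcripts and blocks exceeding
chromEnd are rejected with reasons.

## The fixture generator

`make_benchmark_case` emulates a characterized sample at toy scale:
each planted scenario (matched pair, missed truth, wrong-direction
call, spurious call, intergenic call, one-truth/two-query split) owns
an isolated "unit" on a contig, separated by 15 kb margins so padded
exons and events of different units can never interact.  Within a unit
the gene's exon count and the event's exact length are controlled
(events cover a chosen exon prefix and extend leftwards into intergenic
space), so the length bin and exon bin of every planted event are known
at generation time.  Expected metric tables and filter verdicts are
derived from this bookkeeping — by construction, never by running the
engine — which makes generator-vs-engine agreement a genuine oracle
test.  Default composition: ~25 scenarios over 2 contigs (~1–2 Mb
each), exercising both dosage directions, all default bins, both FP
pathways (direction mismatch and truth-free exon), ignored calls, and
one gap-overlap plus one recurrent-artifact filter hit.  Everything is
driven by a single integer seed; identical seeds give byte-identical
files.

What the fixtures deliberately do not emulate: read-level evidence (no
BAMs; the toolkit consumes calls), mappability structure, paralogy,
overlapping real transcripts, or realistic genome-scale event density.
Passing tests therefore demonstrate the correctness of the matching,
conversion, placement, filtering and counting logic under controlled
geometry — not caller performance on real data, which additionally
depends on sequencing depth, reference artifacts and truth-set
completeness.

`make_reference` produces seeded random ACGT contigs with optional
embedded tandem repeats (a block copied immediately after itself) whose
recorded positions let insertion-to-duplication verification round-trip
at identity 1.0.  `make_artifact_cohort` plants shared artifacts with
±100 bp endpoint jitter — small enough that all pairwise reciprocal
overlaps stay above 0.90 for 5 kb artifacts — plus well-separated
private calls.

## Numerical and edge-case choices

- Interval construction rejects empty/negative spans outright, so no
  downstream division by zero is possible.
- `verify_duplication` tie-breaks (identity, then |offset|, then RIGHT
  before LEFT) are fixed for determinism; identities are exact rational
  values (matches/L) compared against the threshold with `>=`.
- Filter thresholds are inclusive exactly as stated: 500 bp and 10 Mb
  are kept, 499 bp and 10 Mb + 1 dropped; reciprocal overlap uses `>=`.
- The spiking scan advances its cursor past the furthest blocking gene
  end on conflict, guaranteeing termination and left-most feasible
  placement.
- Unknown contigs in overlap probes return empty results, not errors:
  region resources routinely cover fewer contigs than call sets.

## Problem sizes in the test and acceptance suites

Unit suites run on instances of tens of events; the end-to-end property
suite uses 100 randomized classification instances (≤ 50 events, ≤ 200
exons each) against the brute-force triple-loop oracle, 100 generated
benchmark cases for exact planted-metric recovery, 1000-case
duplication-verification grids, 100 random cohorts for the clustering
oracle, and 50 random spiking layouts under the independent audit.  The
whole suite completes in a few seconds on one CPU; sizes were chosen as
the point where further scale stopped changing coverage, and all scale
knobs live in `FixtureSpec` and the test parameters.
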