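# cnvbench

Benchmarking of germline copy-number-variant (CNV) call sets from
short-read whole-genome sequencing, scored the way clinical reporting
works: by the coding exons an event disrupts, not by breakpoint accuracy.

## Who this is for

Clinical bioinformatics teams evaluating WGS CNV callers (or tuning a
high-sensitivity caller's post-filters) for gene-panel reporting, where
the question is *"does the pipeline find every deletion/duplication that
hits a coding exon of a panel gene?"* and missed variants are far more
costly than false positives (which are removed by orthogonal
confirmation).

## The matching model

Calls and truth events are matched through **splice-padded coding
exons** — each coding exon of a canonical transcript extended by 15 bp
of flanking intron to capture splice junctions:

- a query call is a **true positive** iff it overlaps (≥ 1 bp) some
  padded exon that is also overlapped by a truth event of the same
  dosage direction (DEL↔DEL, DUP↔DUP);
- a query overlapping in-scope exons but sharing none with a same-type
  truth event is a **false positive**;
- a query touching no in-scope exon is **ignored** (it can disrupt no
  evaluated coding sequence and enters neither denominator);
- a truth event overlapping ≥ 1 padded exon is **detected** iff a
  same-type query shares one of its exons, otherwise a **false
  negative**; truth events touching no exon are excluded.

Counting is event-level, truth and query sides tallied separately
(GA4GH-style), so a ten-exon event still counts once:

```
sensitivity = TP_truth / (TP_truth + FN)      precision = TP_query / (TP_query + FP)
```

Rates with an empty denominator are reported as null, never 0.  Results
are stratified by event type, event length (0.5–1, 1–5, 1–10, ≥5,
>10 kb) and exons spanned (1, 2–5, >5).

Around this core the package provides:

- **Truth-set preparation** — SV truth sets often encode tandem
  duplications as sequence-resolved insertions.  An insertion is
  reclassified as a DUP when its sequence matches the adjacent reference
  at ≥ 95% ungapped identity, scanning both flanks and positional
  offsets of up to ±2 bp; failures are excluded.  Events are then
  restricted to the evaluated 500 bp – 10 Mb size window.
- **Synthetic gene spiking** — translated copies of real gene exon
  structures planted into high-confidence regions (≥ 100 kb apart,
  avoiding real genes) and directly on top of truth duplications, to
  densify sparse truth sets with scoreable exon overlaps.
- **Artifact filtering** — a multi-rule post-filter for high-sensitivity
  callers: size window, junction-only calls (SVCLAIM=J) above 1 Mb,
  assembly-gap overlap, and ≥ 90% reciprocal overlap with recurrent
  artifacts (direct test, or a two-BED min/max containment surrogate).
  A blacklist builder discovers those recurrent artifacts across a
  cohort by single-linkage clustering.
- **Fixture generation** — seed-reproducible toy references, gene
  models, truth/query call sets with planted TP/FP/FN composition and
  multi-sample artifact cohorts, with expected results computed at
  generation time by construction.

## Worked example

Generate a toy benchmark case and score it:

```
$ cnvbench make-fixture --seed 7 --out-dir fix
$ cnvbench benchmark --query-vcf fix/query.vcf --truth-vcf fix/truth.vcf \
      --genes fix/genes.bed --out-prefix run
sensitivity=0.600 precision=0.625 (truth TP=9 FN=6; query TP=10 FP=6)
```

Of the 15 truth events overlapping exons, 9 were detected by a
same-type query sharing an exon; of the 16 scoreable queries, 10 were
confirmed (2 further calls were fully intergenic and ignored).
`run.metrics.tsv` holds the stratified table:

```
axis        stratum  tp_truth  fn  tp_query  fp  sensitivity  precision
ALL         ALL      9         6   10        6   0.600        0.625
SVTYPE      DEL      6         3   7         3   0.667        0.700
SVTYPE      DUP      3         3   3         3   0.500        0.500
LENGTH_BIN  0.5-1kb  2         3   4         2   0.400        0.667
...
```

Apply the artifact filter using the fixture's planted gap track and
recurrent-artifact blacklist:

```
$ cnvbench filter --vcf fix/query.vcf --out-vcf filtered.vcf \
      --gap-bed fix/gaps.bed --artifact-min-bed fix/artifact_min.bed \
      --artifact-max-bed fix/artifact_max.bed
kept 16/18 calls (2 failed)
```

The two dropped calls are exactly the planted gap-overlap and
recurrent-artifact hits.  Other entry points: `cnvbench prepare-truth`
(insertion→duplication conversion with an audit TSV), `cnvbench
spike-genes`, `cnvbench build-blacklist`, and the same operations as
library functions (`cnvbench.classify`, `cnvbench.verify_duplication`,
…).

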