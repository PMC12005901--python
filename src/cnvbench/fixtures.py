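"""Seed-reproducible synthetic fixtures for every part of the toolkit.

Real benchmarking inputs (a characterized reference cell line's truth
set, gene annotation, multi-sample call sets) are large downloads; these
generators emulate them at toy scale so the whole pipeline is testable
offline.  Crucially, :func:`make_benchmark_case` computes its expected
classification and metric table *at generation time by construction*
(independent bookkeeping of what was planted where), never by running
the benchmark engine — so generator expectations are a genuine oracle
for the engine.

The geometry is arranged in isolated "units" along each contig: every
planted scenario (a matched truth/query pair, a missed truth, a
wrong-direction call, a spurious call, an intergenic call) owns a unit
wide enough that padded exons and events of different units can never
touch.  Within a unit, exon counts and event lengths are controlled
exactly, so length-bin and exon-bin strata of every event are known.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from cnvbench.artifacts import ArtifactRegion
from cnvbench.benchmark import (
    ALL,
    DEFAULT_EXON_BINS,
    DEFAULT_LENGTH_BINS,
    EXON_COUNT_BIN,
    LENGTH_BIN,
    SVTYPE,
    MetricTable,
    StratumSpec,
    default_strata,
)
from cnvbench.genes import GeneModel, write_bed12
from cnvbench.intervals import (
    DEL,
    DEPTH,
    DUP,
    QUERY,
    TRUTH,
    CnvEvent,
    GenomicInterval,
    RegionSet,
)
from cnvbench.io import write_bed, write_fasta, write_sv_vcf


# ---------------------------------------------------------------------------
# Reference fixture


@dataclass(frozen=True)
class TandemSite:
    """A planted tandem repeat: bases [position, position+length) are an
    exact copy of [position-length, position)."""

    chrom: str
    position: int
    length: int


@dataclass
class ReferenceFixture:
    sequences: dict[str, str]
    tandem_sites: list[TandemSite]

    def write(self, path: str | os.PathLike) -> None:
        write_fasta(path, self.sequences)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]


def make_reference(
    seed: int,
    contigs: Optional[Mapping[str, int]] = None,
    tandem_sites_per_contig: int = 0,
    tandem_length: int = 1_000,
) -> ReferenceFixture:
    """Random ACGT reference, optionally with embedded tandem repeats.

    Tandem sites make duplication-verification round trips possible: an
    insertion carrying the repeat's second copy is an exact duplication
    of the reference immediately left of it.  Byte-identical output for
    identical arguments.
    """
    if contigs is None:
        contigs = {"ctg1": 50_000, "ctg2": 50_000}
    for name, length in contigs.items():
        if length < 10_000:
            raise ValueError(f"contig {name}: length {length} < 10 kb")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    sequences: dict[str, str] = {}
    sites: list[TandemSite] = []
    for name, length in contigs.items():
        arr = rng.choice(bases, size=length)
        if tandem_sites_per_contig:
            # evenly spaced, away from contig ends
            step = (length - 4 * tandem_length) // (tandem_sites_per_contig + 1)
            for k in range(1, tandem_sites_per_contig + 1):
                pos = 2 * tandem_length + k * step
                arr[pos : pos + tandem_length] = arr[pos - tandem_length : pos]
                sites.append(TandemSite(name, pos, tandem_length))
        sequences[name] = arr.tobytes().decode()
    return ReferenceFixture(sequences, sites)


# ---------------------------------------------------------------------------
# Benchmark-case fixture


@dataclass(frozen=True)
class PlantedEvent:
    """Generation-time bookkeeping for one planted truth or query event."""

    side: str  # TRUTH or QUERY
    svtype: str
    length: int
    n_exons: int
    outcome: str  # detected/fn for truth; tp/fp/ignored for query
    source_id: str


@dataclass
class FixtureSpec:
    """Planted composition of one benchmark case.

    Counts are per scenario flavor; each planted scenario occupies its
    own isolated unit.  ``n_tp`` plants a truth event plus a query copy;
    ``n_fn`` a truth with no query; ``n_fp_direction`` (keyed by the
    *query's* svtype) a truth of the opposite direction plus a query over
    the same exons; ``n_fp_novel`` a query over exons with no truth;
    ``n_tp_multi`` a three-exon truth matched by two single-exon queries;
    ``n_ignored`` fully intergenic queries.  ``n_gap_hits`` /
    ``n_artifact_hits`` designate that many spurious (fp_novel) queries
    to be covered by a planted gap region / recurrent-artifact entry.
    """

    seed: int = 0
    n_tp: dict = field(default_factory=lambda: {DEL: 5, DUP: 3})
    n_fn: dict = field(default_factory=lambda: {DEL: 2, DUP: 2})
    n_fp_direction: dict = field(default_factory=lambda: {DEL: 1, DUP: 1})
    n_fp_novel: dict = field(default_factory=lambda: {DEL: 2, DUP: 2})
    n_tp_multi: int = 1
    n_ignored: int = 2
    n_gap_hits: int = 1
    n_artifact_hits: int = 1
    n_contigs: int = 2
    exon_length: int = 150
    pad: int = 15
    max_contig_length: Optional[int] = None  # raise if the layout cannot fit

    def __post_init__(self) -> None:
        for d in (self.n_tp, self.n_fn, self.n_fp_direction, self.n_fp_novel):
            if any(v < 0 for v in d.values()):
                raise ValueError("negative planted count")
        total_novel = sum(self.n_fp_novel.values())
        if self.n_gap_hits + self.n_artifact_hits > total_novel:
            raise ValueError(
                "n_gap_hits + n_artifact_hits exceeds the number of "
                "spurious (fp_novel) queries available to host them"
            )


# (exons covered, min length, max length) combinations cycled across
# planted events; lengths exercise every default length bin.
_COMBOS = (
    (1, 600, 950),
    (1, 2_600, 4_400),
    (3, 6_000, 9_400),
    (6, 11_000, 14_500),
    (1, 510, 990),
    (3, 5_400, 9_900),
)

_UNIT_MARGIN = 15_000  # intergenic slack on each side of a unit's gene


@dataclass
class BenchmarkCase:
    """A generated benchmark case plus its construction-time expectations."""

    spec: FixtureSpec
    genes: list[GeneModel]
    truth_events: list[CnvEvent]
    query_events: list[CnvEvent]
    contig_lengths: dict[str, int]
    gap_regions: RegionSet
    artifact_regions: list[ArtifactRegion]
    planted: list[PlantedEvent]
    expected_verdicts: dict[str, tuple[str, ...]]  # query id -> failed rules

    def expected_metric_table(
        self, strata: Optional[Sequence[StratumSpec]] = None
    ) -> MetricTable:
        """Stratified counts derived purely from generation bookkeeping."""
        if strata is None:
            strata = default_strata()
        rows = []
        for spec in strata:
            if spec.axis == ALL:
                labels = ["ALL"]
            elif spec.axis == SVTYPE:
                labels = [DEL, DUP]
            else:
                labels = [b.label for b in spec.bins]
            for lab in labels:
                tp_truth = fn = tp_query = fp = 0
                for rec in self.planted:
                    if rec.outcome == "ignored":
                        continue
                    if spec.axis == SVTYPE and rec.svtype != lab:
                        continue
                    if spec.axis == LENGTH_BIN:
                        bin_ = next(b for b in spec.bins if b.label == lab)
                        if not bin_.contains(rec.length):
                            continue
                    if spec.axis == EXON_COUNT_BIN:
                        bin_ = next(b for b in spec.bins if b.label == lab)
                        if not bin_.contains(rec.n_exons):
                            continue
                    if rec.side == TRUTH:
                        if rec.outcome == "detected":
                            tp_truth += 1
                        else:
                            fn += 1
                    else:
                        if rec.outcome == "tp":
                            tp_query += 1
                        else:
                            fp += 1
                rows.append(
                    {
                        "axis": spec.axis,
                        "stratum": lab,
                        "tp_truth": tp_truth,
                        "fn": fn,
                        "tp_query": tp_query,
                        "fp": fp,
                        "sensitivity": tp_truth / (tp_truth + fn)
                        if tp_truth + fn
                        else None,
                        "precision": tp_query / (tp_query + fp)
                        if tp_query + fp
                        else None,
                    }
                )
        return MetricTable(rows)

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Emit VCF/BED12/BED files plus an expectations JSON."""
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "truth_vcf": os.path.join(outdir, "truth.vcf"),
            "query_vcf": os.path.join(outdir, "query.vcf"),
            "genes_bed12": os.path.join(outdir, "genes.bed"),
            "gaps_bed": os.path.join(outdir, "gaps.bed"),
            "artifact_min_bed": os.path.join(outdir, "artifact_min.bed"),
            "artifact_max_bed": os.path.join(outdir, "artifact_max.bed"),
            "expectations_json": os.path.join(outdir, "expectations.json"),
        }
        write_sv_vcf(paths["truth_vcf"], self.truth_events, self.contig_lengths)
        write_sv_vcf(paths["query_vcf"], self.query_events, self.contig_lengths)
        write_bed12(paths["genes_bed12"], self.genes)
        write_bed(paths["gaps_bed"], list(self.gap_regions))
        from cnvbench.artifacts import write_blacklist_beds

        write_blacklist_beds(
            self.artifact_regions, paths["artifact_min_bed"], paths["artifact_max_bed"]
        )
        table = self.expected_metric_table()
        payload = {
            "seed": self.spec.seed,
            "metrics": json.loads(table.frame.to_json(orient="records")),
            "verdicts": {k: list(v) for k, v in self.expected_verdicts.items()},
        }
        with open(paths["expectations_json"], "w") as fh:
            json.dump(payload, fh, indent=2)
        return paths


def make_benchmark_case(spec: FixtureSpec) -> BenchmarkCase:
    """Generate genes, truth and query call sets with known composition.

    Every scenario is planted in an isolated unit so that classification
    is forced by construction: a TP query shares exons with its truth
    (it is an exact copy, or a single-exon sub-call in the multi-query
    flavor); a wrong-direction FP sits on a truth of the opposite dosage
    direction; a spurious FP sits on exons no truth touches; ignored
    queries are fully intergenic.
    """
    rng = random.Random(spec.seed)
    exon_len = spec.exon_length

    # Build the scenario list, then shuffle so unit order varies by seed.
    scenarios: list[tuple[str, str]] = []
    for svtype, n in spec.n_tp.items():
        scenarios += [("tp", svtype)] * n
    for svtype, n in spec.n_fn.items():
        scenarios += [("fn", svtype)] * n
    for svtype, n in spec.n_fp_direction.items():
        scenarios += [("fp_direction", svtype)] * n
    novel: list[tuple[str, str]] = []
    for svtype, n in spec.n_fp_novel.items():
        novel += [("fp_novel", svtype)] * n
    scenarios += novel
    scenarios += [("tp_multi", DEL if i % 2 == 0 else DUP) for i in range(spec.n_tp_multi)]
    scenarios += [("ignored", DEL)] * spec.n_ignored
    rng.shuffle(scenarios)

    combo_cycle = list(_COMBOS)
    rng.shuffle(combo_cycle)

    genes: list[GeneModel] = []
    truth_events: list[CnvEvent] = []
    query_events: list[CnvEvent] = []
    planted: list[PlantedEvent] = []
    gap_intervals: list[GenomicInterval] = []
    artifact_regions: list[ArtifactRegion] = []
    novel_queries: list[CnvEvent] = []  # candidates to host gap/artifact hits

    contigs = [f"ctg{i+1}" for i in range(spec.n_contigs)]
    cursors = {c: 0 for c in contigs}
    counter = {"t": 0, "q": 0, "g": 0}

    def next_id(kind: str) -> str:
        counter[kind] += 1
        return f"{kind}{counter[kind]:04d}"

    def plant_gene(chrom: str, start: int, n_exons: int, intron: int) -> GeneModel:
        exons = []
        pos = start
        for _ in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + exon_len))
            pos += exon_len + intron
        return GeneModel(
            name=next_id("g"),
            chrom=chrom,
            strand=rng.choice("+-"),
            exons=tuple(exons),
        )

    def carve_event(gene: GeneModel, k: int, length: int) -> GenomicInterval:
        """Interval of exactly ``length`` covering exons 0..k-1 of the gene,
        extended leftwards into intergenic space (never touching the next
        exon's padded region)."""
        covered = gene.exons[k - 1].end - gene.exons[0].start
        assert length >= covered, "combo length below covered exon span"
        return GenomicInterval(
            gene.chrom, gene.exons[0].start - (length - covered), gene.exons[k - 1].end
        )

    for i, (flavor, svtype) in enumerate(scenarios):
        chrom = contigs[i % len(contigs)]
        origin = cursors[chrom]
        intron = rng.randint(1_800, 2_400)
        k, lo, hi = combo_cycle[i % len(combo_cycle)]
        if flavor in ("tp_multi",):
            k = 3
            lo, hi = 6_000, 9_400
        gene_exons = min(6, k + 1) if flavor != "ignored" else 0
        gene_start = origin + _UNIT_MARGIN

        if flavor == "ignored":
            iv = GenomicInterval(chrom, gene_start, gene_start + 1_000)
            qid = next_id("q")
            query_events.append(
                CnvEvent(iv, svtype, iv.length, DEPTH, qid, QUERY)
            )
            planted.append(PlantedEvent(QUERY, svtype, iv.length, 0, "ignored", qid))
            cursors[chrom] = gene_start + 1_000 + _UNIT_MARGIN
            continue

        gene = plant_gene(chrom, gene_start, gene_exons, intron)
        genes.append(gene)
        covered = gene.exons[k - 1].end - gene.exons[0].start
        length = rng.randint(max(lo, covered), max(hi, covered))
        iv = carve_event(gene, k, length)

        if flavor == "tp":
            tid, qid = next_id("t"), next_id("q")
            truth_events.append(CnvEvent(iv, svtype, iv.length, source_id=tid, origin=TRUTH))
            query_events.append(CnvEvent(iv, svtype, iv.length, DEPTH, qid, QUERY))
            planted.append(PlantedEvent(TRUTH, svtype, iv.length, k, "detected", tid))
            planted.append(PlantedEvent(QUERY, svtype, iv.length, k, "tp", qid))
        elif flavor == "fn":
            tid = next_id("t")
            truth_events.append(CnvEvent(iv, svtype, iv.length, source_id=tid, origin=TRUTH))
            planted.append(PlantedEvent(TRUTH, svtype, iv.length, k, "fn", tid))
        elif flavor == "fp_direction":
            other = DUP if svtype == DEL else DEL
            tid, qid = next_id("t"), next_id("q")
            truth_events.append(CnvEvent(iv, other, iv.length, source_id=tid, origin=TRUTH))
            query_events.append(CnvEvent(iv, svtype, iv.length, DEPTH, qid, QUERY))
            planted.append(PlantedEvent(TRUTH, other, iv.length, k, "fn", tid))
            planted.append(PlantedEvent(QUERY, svtype, iv.length, k, "fp", qid))
        elif flavor == "fp_novel":
            qid = next_id("q")
            q = CnvEvent(iv, svtype, iv.length, DEPTH, qid, QUERY)
            query_events.append(q)
            novel_queries.append(q)
            planted.append(PlantedEvent(QUERY, svtype, iv.length, k, "fp", qid))
        elif flavor == "tp_multi":
            tid = next_id("t")
            truth_events.append(CnvEvent(iv, svtype, iv.length, source_id=tid, origin=TRUTH))
            planted.append(PlantedEvent(TRUTH, svtype, iv.length, k, "detected", tid))
            # two single-exon sub-calls: exon 0 extended left (intergenic),
            # exon k-1 extended right (intergenic, it is not the last exon
            # of the gene only when gene_exons > k; extension stays in the
            # intron short of the next padded exon)
            sub_len = rng.randint(600, 950)
            q1_iv = GenomicInterval(
                chrom, gene.exons[0].start - (sub_len - exon_len), gene.exons[0].end
            )
            right_room = intron - spec.pad - 1
            sub2 = min(rng.randint(600, 950), exon_len + right_room)
            q2_iv = GenomicInterval(
                chrom, gene.exons[k - 1].start, gene.exons[k - 1].start + sub2
            )
            for q_iv in (q1_iv, q2_iv):
                qid = next_id("q")
                query_events.append(CnvEvent(q_iv, svtype, q_iv.length, DEPTH, qid, QUERY))
                planted.append(PlantedEvent(QUERY, svtype, q_iv.length, 1, "tp", qid))
        cursors[chrom] = gene.span.end + _UNIT_MARGIN

    if spec.max_contig_length is not None:
        worst = max(cursors.values())
        if worst > spec.max_contig_length:
            raise ValueError(
                f"layout needs {worst} bp but max_contig_length is "
                f"{spec.max_contig_length}: too many planted scenarios"
            )

    # Designate gap and artifact hits among the spurious queries.
    expected_verdicts: dict[str, tuple[str, ...]] = {
        q.source_id: () for q in query_events
    }
    hosts = list(novel_queries)
    rng.shuffle(hosts)
    for q in hosts[: spec.n_gap_hits]:
        mid = (q.interval.start + q.interval.end) // 2
        gap_intervals.append(GenomicInterval(q.chrom, mid, mid + 50))
        expected_verdicts[q.source_id] = ("GAP_OVERLAP",)
    for q in hosts[spec.n_gap_hits : spec.n_gap_hits + spec.n_artifact_hits]:
        artifact_regions.append(
            ArtifactRegion(
                interval=q.interval,
                svtype=q.svtype,
                recurrence=3,
                member_ids=(q.source_id,),
            )
        )
        expected_verdicts[q.source_id] = ("RECURRENT_ARTIFACT",)

    contig_lengths = {c: cursors[c] + _UNIT_MARGIN for c in contigs}
    return BenchmarkCase(
        spec=spec,
        genes=genes,
        truth_events=truth_events,
        query_events=query_events,
        contig_lengths=contig_lengths,
        gap_regions=RegionSet(gap_intervals, label="gap-track"),
        artifact_regions=artifact_regions,
        planted=planted,
        expected_verdicts=expected_verdicts,
    )


# ---------------------------------------------------------------------------
# Artifact-cohort fixture


@dataclass
class ArtifactCohort:
    callsets: dict[str, list[CnvEvent]]
    shared_intervals: list[GenomicInterval]  # one per planted recurrent artifact
    contig_lengths: dict[str, int]


def make_artifact_cohort(
    seed: int,
    n_samples: int = 5,
    n_shared: int = 3,
    n_private: int = 3,
    jitter: int = 100,
    artifact_length: int = 5_000,
) -> ArtifactCohort:
    """A multi-sample cohort with planted recurrent artifacts.

    Each shared artifact appears in every sample with endpoint jitter of
    at most ``jitter`` bases, which keeps all pairwise reciprocal
    overlaps above 0.90 for the default sizes; private calls are placed
    far apart so they never cluster.
    """
    if jitter * 4 >= artifact_length:
        raise ValueError("jitter too large relative to artifact length")
    rng = random.Random(seed)
    chrom = "ctg_art"
    spacing = 5 * artifact_length
    shared = [
        GenomicInterval(chrom, (i + 1) * spacing, (i + 1) * spacing + artifact_length)
        for i in range(n_shared)
    ]
    private_origin = (n_shared + 2) * spacing
    callsets: dict[str, list[CnvEvent]] = {}
    samples = [f"sample{i+1}" for i in range(n_samples)]
    for si, sample in enumerate(samples):
        calls: list[CnvEvent] = []
        for ai, base in enumerate(shared):
            d1 = rng.randint(-jitter, jitter)
            d2 = rng.randint(-jitter, jitter)
            iv = GenomicInterval(chrom, base.start + d1, base.end + d2)
            svtype = DEL if ai % 2 == 0 else DUP
            calls.append(
                CnvEvent(iv, svtype, iv.length, source_id=f"{sample}_shared{ai}")
            )
        for pi in range(n_private):
            start = private_origin + (si * n_private + pi) * spacing
            iv = GenomicInterval(chrom, start, start + artifact_length)
            calls.append(
                CnvEvent(iv, DEL, iv.length, source_id=f"{sample}_private{pi}")
            )
        callsets[sample] = calls
    end = private_origin + (n_samples * n_private + 2) * spacing
    return ArtifactCohort(
        callsets=callsets,
        shared_intervals=shared,
        contig_lengths={chrom: end},
    )
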