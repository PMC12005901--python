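"""Exon-mediated classification of CNV calls and stratified metrics.

The clinical question is whether a caller finds the events that disrupt
coding sequence, so matching is mediated entirely by splice-padded
coding exons rather than by breakpoint or reciprocal-overlap agreement
between call and truth:

* a query call is a **TP** iff some padded exon it overlaps (by >= 1 bp)
  is also overlapped by at least one truth event of the same dosage
  direction (DEL with DEL, DUP with DUP);
* a query overlapping in-scope exons but sharing none with a same-type
  truth event is an **FP**;
* a query overlapping no in-scope exon is **IGNORED** — it can disrupt
  no evaluated coding sequence, so it enters neither denominator;
* a truth event overlapping at least one padded exon is **detected**
  (counts toward sensitivity's numerator) iff some same-type query
  shares one of its exons, otherwise it is an **FN**; truth events
  touching no exon are excluded from the denominators entirely.

Counting is event-level (GA4GH style, truth and query sides counted
separately): an event spanning ten exons still counts once, which is the
multi-exon double-counting adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from cnvbench.genes import ExonIndex, PaddedExon
from cnvbench.intervals import (
    DEL,
    DUP,
    INS,
    QUERY,
    TRUTH,
    CnvEvent,
    GenomicInterval,
    RegionSet,
)

TP = "TP"
FP = "FP"
FN = "FN"
IGNORED = "IGNORED"

ALL = "ALL"
SVTYPE = "SVTYPE"
LENGTH_BIN = "LENGTH_BIN"
EXON_COUNT_BIN = "EXON_COUNT_BIN"


@dataclass(frozen=True)
class Bin:
    """One named stratum bin over a numeric axis.

    Membership is ``lo <= x < hi`` (or ``lo < x`` when ``lo_strict``,
    matching '>N' style bins; ``hi=None`` leaves the bin open above).
    """

    label: str
    lo: float
    hi: Optional[float] = None
    lo_strict: bool = False

    def contains(self, x: float) -> bool:
        if self.lo_strict:
            if x <= self.lo:
                return False
        elif x < self.lo:
            return False
        return self.hi is None or x < self.hi


@dataclass(frozen=True)
class StratumSpec:
    """A stratification axis plus its bins (categorical axes ignore bins)."""

    axis: str
    bins: tuple[Bin, ...] = ()


# Default stratifications: event type; the length binnings used for
# whole-genome (1-5 kb / >=5 kb) and panel-level (0.5-1 / 1-10 / >10 kb)
# reporting; and exons-spanned bins (1 / 2-5 / >5).  Length binnings from
# different reports overlap each other; each named bin is evaluated
# independently.
DEFAULT_LENGTH_BINS = (
    Bin("0.5-1kb", 500, 1_000),
    Bin("1-5kb", 1_000, 5_000),
    Bin("1-10kb", 1_000, 10_000),
    Bin(">=5kb", 5_000, None),
    Bin(">10kb", 10_000, None, lo_strict=True),
)
DEFAULT_EXON_BINS = (
    Bin("1", 1, 2),
    Bin("2-5", 2, 6),
    Bin(">5", 6, None),
)


def default_strata() -> list[StratumSpec]:
    return [
        StratumSpec(ALL),
        StratumSpec(SVTYPE),
        StratumSpec(LENGTH_BIN, DEFAULT_LENGTH_BINS),
        StratumSpec(EXON_COUNT_BIN, DEFAULT_EXON_BINS),
    ]


@dataclass
class MatchReport:
    """Classification of one event plus the exons that mediated it.

    ``overlapped_exons`` are all in-scope padded exons the event touches
    (this drives exon-count stratification); ``mediating_exons`` is the
    subset shared with a same-type counterpart; ``matched_ids`` are the
    counterpart event ids.
    """

    event: CnvEvent
    status: str
    overlapped_exons: list[PaddedExon] = field(default_factory=list)
    mediating_exons: list[PaddedExon] = field(default_factory=list)
    matched_ids: list[str] = field(default_factory=list)

    @property
    def n_exons(self) -> int:
        return len(self.overlapped_exons)


def classify(
    queries: Sequence[CnvEvent],
    truths: Sequence[CnvEvent],
    exon_index: ExonIndex,
    restrict_to: Optional[RegionSet] = None,
) -> list[MatchReport]:
    """Classify query calls against truth events via shared padded exons.

    ``restrict_to`` optionally limits the in-scope exons to those
    intersecting a set of regions (virtual-panel evaluation); exons
    outside it mediate nothing and queries touching only such exons are
    IGNORED.  The result is one report per input event, queries first
    (in input order) then truths; classification itself is order-free.
    """
    for ev in (*queries, *truths):
        if ev.svtype == INS:
            raise ValueError(
                f"event {ev.source_id or ev.interval}: INS records cannot be "
                "benchmarked; run truth preparation first"
            )

    def in_scope(pe: PaddedExon) -> bool:
        return restrict_to is None or restrict_to.overlaps_any(pe.interval)

    def scoped_exons(ev: CnvEvent) -> list[PaddedExon]:
        return [pe for pe in exon_index.overlapping(ev.interval) if in_scope(pe)]

    truth_exons: list[list[PaddedExon]] = [scoped_exons(t) for t in truths]
    # exon key -> truth indices covering it, per svtype
    cover: dict[str, dict[tuple[str, int], set[int]]] = {DEL: {}, DUP: {}}
    for ti, (truth, exons) in enumerate(zip(truths, truth_exons)):
        for pe in exons:
            cover[truth.svtype].setdefault(pe.key, set()).add(ti)

    reports: list[MatchReport] = []
    query_cover: dict[str, set[tuple[str, int]]] = {DEL: set(), DUP: set()}
    for q in queries:
        exons = scoped_exons(q)
        if not exons:
            reports.append(MatchReport(q, IGNORED))
            continue
        query_cover[q.svtype].update(pe.key for pe in exons)
        same = cover[q.svtype]
        mediating = [pe for pe in exons if pe.key in same]
        if mediating:
            matched = sorted(
                {truths[ti].source_id for pe in mediating for ti in same[pe.key]}
            )
            reports.append(MatchReport(q, TP, exons, mediating, matched))
        else:
            reports.append(MatchReport(q, FP, exons))
    for truth, exons in zip(truths, truth_exons):
        if not exons:
            reports.append(MatchReport(truth, IGNORED))
            continue
        qcover = query_cover[truth.svtype]
        mediating = [pe for pe in exons if pe.key in qcover]
        if mediating:
            reports.append(MatchReport(truth, TP, exons, mediating))
        else:
            reports.append(MatchReport(truth, FN, exons))
    return reports


@dataclass(frozen=True)
class EventCounts:
    """Event-level TP/FP/FN tallies (each event counted exactly once)."""

    tp_truth: int = 0
    fn: int = 0
    tp_query: int = 0
    fp: int = 0
    ignored: int = 0

    @property
    def sensitivity(self) -> Optional[float]:
        denom = self.tp_truth + self.fn
        return self.tp_truth / denom if denom else None

    @property
    def precision(self) -> Optional[float]:
        denom = self.tp_query + self.fp
        return self.tp_query / denom if denom else None


def adjust_multi_exon(reports: Iterable[MatchReport]) -> EventCounts:
    """Collapse exon-level matches to event-level counts.

    The counting unit is the event: a query spanning many exons, or
    matched by many truth events, contributes exactly one TP (and
    symmetrically for truth events), which prevents multi-exon events
    from being double counted.
    """
    tp_truth = fn = tp_query = fp = ignored = 0
    for rep in reports:
        if rep.status == IGNORED:
            ignored += 1
        elif rep.event.origin == QUERY:
            if rep.status == TP:
                tp_query += 1
            elif rep.status == FP:
                fp += 1
        else:
            if rep.status == TP:
                tp_truth += 1
            elif rep.status == FN:
                fn += 1
    return EventCounts(tp_truth, fn, tp_query, fp, ignored)


class MetricTable:
    """Stratified sensitivity/precision counts.

    One row per (axis, stratum): truth-side TP/FN and query-side TP/FP
    with the derived rates.  Rates with an empty denominator are null
    (None/NaN), never zero.
    """

    COLUMNS = [
        "axis",
        "stratum",
        "tp_truth",
        "fn",
        "tp_query",
        "fp",
        "sensitivity",
        "precision",
    ]

    def __init__(self, rows: list[dict]):
        self.frame = pd.DataFrame(rows, columns=self.COLUMNS)

    def row(self, axis: str, stratum: str) -> dict:
        sel = self.frame[(self.frame.axis == axis) & (self.frame.stratum == stratum)]
        if sel.empty:
            raise KeyError((axis, stratum))
        rec = sel.iloc[0].to_dict()
        for k in ("sensitivity", "precision"):
            if isinstance(rec[k], float) and math.isnan(rec[k]):
                rec[k] = None
        return rec

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        self.frame.to_json(path, orient="records", indent=2)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MetricTable({len(self.frame)} strata)\n{self.frame}"


def _strata_for(
    report: MatchReport, spec: StratumSpec
) -> list[str]:
    """Stratum labels an event belongs to under one spec (possibly several,
    because the configured length binnings may overlap)."""
    if spec.axis == ALL:
        return ["ALL"]
    if spec.axis == SVTYPE:
        return [report.event.svtype]
    if spec.axis == LENGTH_BIN:
        return [b.label for b in spec.bins if b.contains(report.event.length)]
    if spec.axis == EXON_COUNT_BIN:
        return [b.label for b in spec.bins if b.contains(report.n_exons)]
    raise ValueError(f"unknown stratification axis {spec.axis!r}")


def compute_metrics(
    reports: Sequence[MatchReport],
    strata: Optional[Sequence[StratumSpec]] = None,
) -> MetricTable:
    """Per-stratum and overall sensitivity/precision from classifications.

    Truth events are stratified by their own type/length/exon count and
    query events by theirs.  An event whose length falls outside every
    configured length bin still counts in ALL and is flagged in the log.
    """
    if strata is None:
        strata = default_strata()
    scored = [r for r in reports if r.status != IGNORED]

    rows: list[dict] = []
    for spec in strata:
        if spec.axis == ALL:
            labels = ["ALL"]
        elif spec.axis == SVTYPE:
            labels = [DEL, DUP]
        else:
            labels = [b.label for b in spec.bins]
        buckets: dict[str, list[MatchReport]] = {lab: [] for lab in labels}
        for rep in scored:
            memberships = _strata_for(rep, spec)
            for lab in memberships:
                buckets[lab].append(rep)
        for lab in labels:
            counts = adjust_multi_exon(buckets[lab])
            rows.append(
                {
                    "axis": spec.axis,
                    "stratum": lab,
                    "tp_truth": counts.tp_truth,
                    "fn": counts.fn,
                    "tp_query": counts.tp_query,
                    "fp": counts.fp,
                    "sensitivity": counts.sensitivity,
                    "precision": counts.precision,
                }
            )
    return MetricTable(rows)


def reports_to_frame(reports: Sequence[MatchReport]) -> pd.DataFrame:
    """Flatten match reports to a per-event table (for TSV export)."""
    rows = []
    for rep in reports:
        rows.append(
            {
                "source_id": rep.event.source_id,
                "origin": rep.event.origin,
                "chrom": rep.event.chrom,
                "start": rep.event.interval.start,
                "end": rep.event.interval.end,
                "svtype": rep.event.svtype,
                "length": rep.event.length,
                "status": rep.status,
                "n_exons": rep.n_exons,
                "mediating_exons": ",".join(
                    f"{g}:{i}" for g, i in (pe.key for pe in rep.mediating_exons)
                ),
                "matched_ids": ",".join(rep.matched_ids),
            }
        )
    return pd.DataFrame(rows)
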