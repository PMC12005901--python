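"""Post-caller filtering for high-sensitivity CNV call sets.

High-sensitivity callers trade precision for recall; most of the excess
false positives are systematic and can be removed without touching true
calls.  The filter applies five independent rules:

* ``SIZE_MIN`` / ``SIZE_MAX`` — events below 500 bp (dominated by small
  false positives) or above 10 Mb (recurrent breakpoint artifacts
  spanning centromeres/telomeres) are excluded;
* ``JUNCTION_LONG`` — calls supported solely by junction reads
  (SVCLAIM=J) above 1 Mb are excluded, since true calls in that range
  generally exhibit depth support;
* ``GAP_OVERLAP`` — calls overlapping assembly-gap regions
  (centromeres/telomeres, the genome browser "gap" track) by >= 1 bp;
* ``RECURRENT_ARTIFACT`` — calls matching a same-type catalogued
  artifact at reciprocal overlap >= 0.90.  The direct reciprocal-overlap
  test is the default; a two-BED containment mode (call must contain the
  cluster's minimum interval and be contained by its maximum interval)
  is provided for compatibility with filter engines that can only test
  containment against BED files.

All failed rules are recorded for every call, so the rule order never
changes the kept set.  The blacklist builder discovers recurrent
artifacts across samples by single-linkage clustering of same-type calls
under the reciprocal-overlap relation.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from cnvbench.intervals import (
    DEL,
    DUP,
    JUNCTION,
    CnvEvent,
    GenomicInterval,
    RegionSet,
    reciprocal_overlap,
)
from cnvbench.io import write_bed

logger = logging.getLogger(__name__)

SIZE_MIN = "SIZE_MIN"
SIZE_MAX = "SIZE_MAX"
JUNCTION_LONG = "JUNCTION_LONG"
GAP_OVERLAP = "GAP_OVERLAP"
RECURRENT_ARTIFACT = "RECURRENT_ARTIFACT"

RECIPROCAL_MODE = "reciprocal"
TWO_BED_MODE = "two-bed"


@dataclass(frozen=True)
class ArtifactRegion:
    """A recurrent-artifact cluster discovered across samples.

    ``interval`` is the representative span (median endpoints over the
    cluster members); ``min_interval``/``max_interval`` are the members'
    intersection and union, realizing the two-BED containment test.
    """

    interval: GenomicInterval
    svtype: str
    recurrence: int
    member_ids: tuple[str, ...]
    min_interval: GenomicInterval = None  # type: ignore[assignment]
    max_interval: GenomicInterval = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.min_interval is None:
            object.__setattr__(self, "min_interval", self.interval)
        if self.max_interval is None:
            object.__setattr__(self, "max_interval", self.interval)


@dataclass
class FilterConfig:
    """Tunable thresholds and region resources for the filter.

    Lengths are in bases.  ``artifact_regions`` is the recurrent-artifact
    catalogue (with min/max intervals for two-BED mode);
    ``artifact_mode`` selects how the >= 90% reciprocal-overlap criterion
    is evaluated.
    """

    min_len: int = 500
    max_len: int = 10_000_000
    junction_only_max_len: int = 1_000_000
    gap_regions: Optional[RegionSet] = None
    artifact_regions: Sequence[ArtifactRegion] = ()
    recip_threshold: float = 0.90
    artifact_mode: str = RECIPROCAL_MODE

    def __post_init__(self) -> None:
        if not (0 < self.min_len < self.junction_only_max_len < self.max_len):
            raise ValueError(
                "require 0 < min_len < junction_only_max_len < max_len"
            )
        if not (0 < self.recip_threshold <= 1):
            raise ValueError("recip_threshold must be in (0, 1]")
        if self.artifact_mode not in (RECIPROCAL_MODE, TWO_BED_MODE):
            raise ValueError(f"unknown artifact mode {self.artifact_mode!r}")


@dataclass
class FilterVerdict:
    """Keep/drop decision for one call with every failed rule recorded."""

    event: CnvEvent
    failed_rules: list[str] = field(default_factory=list)

    @property
    def kept(self) -> bool:
        return not self.failed_rules


class _ArtifactIndex:
    def __init__(self, regions: Sequence[ArtifactRegion]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for region in regions:
            key = (region.svtype, region.max_interval.chrom)
            self._trees.setdefault(key, IntervalTree()).addi(
                region.max_interval.start, region.max_interval.end, region
            )

    def candidates(self, ev: CnvEvent) -> list[ArtifactRegion]:
        tree = self._trees.get((ev.svtype, ev.chrom))
        if tree is None:
            return []
        return [h.data for h in tree.overlap(ev.interval.start, ev.interval.end)]


def _artifact_hit(ev: CnvEvent, region: ArtifactRegion, config: FilterConfig) -> bool:
    if config.artifact_mode == RECIPROCAL_MODE:
        return reciprocal_overlap(ev.interval, region.interval) >= config.recip_threshold
    return ev.interval.contains(region.min_interval) and region.max_interval.contains(
        ev.interval
    )


def apply_filters(
    calls: Iterable[CnvEvent], config: FilterConfig
) -> list[FilterVerdict]:
    """Evaluate every rule against every call; a call is kept iff it
    fails none.

    Rules are evaluated in a fixed order (size, junction, gap, artifact)
    but all failures are recorded.  Calls with an UNKNOWN evidence claim
    are never hit by the junction-only rule.  Each verdict depends only
    on its own call, so filtering is idempotent and per-call independent.
    """
    artifact_index = _ArtifactIndex(config.artifact_regions)
    verdicts: list[FilterVerdict] = []
    for ev in calls:
        failed: list[str] = []
        if ev.length < config.min_len:
            failed.append(SIZE_MIN)
        if ev.length > config.max_len:
            failed.append(SIZE_MAX)
        if ev.claim == JUNCTION and ev.length > config.junction_only_max_len:
            failed.append(JUNCTION_LONG)
        if config.gap_regions is not None and config.gap_regions.overlaps_any(ev.interval):
            failed.append(GAP_OVERLAP)
        if any(
            _artifact_hit(ev, region, config)
            for region in artifact_index.candidates(ev)
        ):
            failed.append(RECURRENT_ARTIFACT)
        verdicts.append(FilterVerdict(ev, failed))
    return verdicts


# ---------------------------------------------------------------------------
# Blacklist discovery


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_blacklist(
    callsets: Mapping[str, Sequence[CnvEvent]],
    min_recurrence: int = 2,
    recip_threshold: float = 0.90,
) -> list[ArtifactRegion]:
    """Discover recurrent artifacts across a cohort of call sets.

    Same-type calls from all samples are single-linkage clustered under
    ``reciprocal_overlap >= recip_threshold``; clusters seen in at least
    ``min_recurrence`` distinct samples become artifact regions.  The
    representative interval takes the median start and end of the
    members; the min/max intervals are their intersection and union.
    The result is invariant to sample ordering.
    """
    if len(callsets) < 2:
        raise ValueError("blacklist discovery requires call sets from >= 2 samples")
    if min_recurrence > len(callsets):
        logger.warning(
            "min_recurrence %d exceeds sample count %d; blacklist will be empty",
            min_recurrence,
            len(callsets),
        )
        return []

    # canonical ordering makes the result independent of dict order
    members: list[tuple[str, CnvEvent]] = sorted(
        ((sample, ev) for sample, calls in callsets.items() for ev in calls),
        key=lambda it: (
            it[1].svtype,
            it[1].chrom,
            it[1].interval.start,
            it[1].interval.end,
            it[0],
            it[1].source_id,
        ),
    )
    uf = _UnionFind(len(members))
    by_group: dict[tuple[str, str], list[int]] = {}
    for i, (_, ev) in enumerate(members):
        by_group.setdefault((ev.svtype, ev.chrom), []).append(i)
    for idxs in by_group.values():
        for a_pos, i in enumerate(idxs):
            iv_i = members[i][1].interval
            for j in idxs[a_pos + 1 :]:
                iv_j = members[j][1].interval
                if iv_j.start >= iv_i.end:
                    break  # sorted by start: no later interval overlaps i
                if reciprocal_overlap(iv_i, iv_j) >= recip_threshold:
                    uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(members)):
        clusters.setdefault(uf.find(i), []).append(i)

    regions: list[ArtifactRegion] = []
    for idxs in clusters.values():
        samples = {members[i][0] for i in idxs}
        if len(samples) < min_recurrence:
            continue
        events = [members[i][1] for i in idxs]
        chrom = events[0].chrom
        svtype = events[0].svtype
        starts = sorted(ev.interval.start for ev in events)
        ends = sorted(ev.interval.end for ev in events)
        rep = GenomicInterval(
            chrom,
            int(statistics.median(starts)),
            int(statistics.median(ends)),
        )
        inter_start, inter_end = max(starts), min(ends)
        if inter_start < inter_end:
            min_iv = GenomicInterval(chrom, inter_start, inter_end)
        else:
            # degenerate chain cluster with empty common core; fall back to
            # the representative so the two-BED test stays well defined
            min_iv = rep
        max_iv = GenomicInterval(chrom, min(starts), max(ends))
        regions.append(
            ArtifactRegion(
                interval=rep,
                svtype=svtype,
                recurrence=len(samples),
                member_ids=tuple(
                    sorted(f"{members[i][0]}:{members[i][1].source_id}" for i in idxs)
                ),
                min_interval=min_iv,
                max_interval=max_iv,
            )
        )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.svtype))
    return regions


def write_blacklist_beds(
    regions: Sequence[ArtifactRegion], min_path, max_path
) -> None:
    """Emit the minimum- and maximum-overlap BED pair (name column carries
    cluster id, svtype and recurrence, pairing the two files by line)."""
    names = [
        f"artifact{i}|{r.svtype}|{r.recurrence}" for i, r in enumerate(regions)
    ]
    write_bed(min_path, [r.min_interval for r in regions], names)
    write_bed(max_path, [r.max_interval for r in regions], names)


def read_blacklist_beds(min_path, max_path) -> list[ArtifactRegion]:
    """Reconstruct artifact regions from a min/max BED pair."""
    def rows(path):
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                yield GenomicInterval(f[0], int(f[1]), int(f[2])), f[3] if len(f) > 3 else ""

    regions = []
    for (min_iv, name), (max_iv, name2) in zip(rows(min_path), rows(max_path)):
        if name != name2:
            raise ValueError(f"min/max BED name mismatch: {name!r} vs {name2!r}")
        parts = name.split("|")
        svtype = parts[1] if len(parts) > 1 else DEL
        recurrence = int(parts[2]) if len(parts) > 2 else 0
        rep = GenomicInterval(
            max_iv.chrom,
            (min_iv.start + max_iv.start) // 2,
            (min_iv.end + max_iv.end) // 2,
        )
        regions.append(
            ArtifactRegion(
                interval=rep,
                svtype=svtype,
                recurrence=recurrence,
                member_ids=(),
                min_interval=min_iv,
                max_interval=max_iv,
            )
        )
    return regions
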