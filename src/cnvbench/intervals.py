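"""Genomic interval data model and interval arithmetic.

All coordinates inside the package are 0-based half-open ``[start, end)``.
VCF positions are converted on read (``POS - 1``) and on write (``+ 1``);
BED coordinates pass through unchanged.  Empty intervals are rejected at
construction so every downstream length division is safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

# Dosage directions / structural-variant types handled by the toolkit.
DEL = "DEL"
DUP = "DUP"
INS = "INS"
SVTYPES = frozenset({DEL, DUP, INS})

# Evidence claims (how the caller supports an event).  Junction-only calls
# are split/discordant-read calls with no depth support; DRAGEN marks them
# with SVCLAIM=J in the VCF INFO field.
DEPTH = "DEPTH"
JUNCTION = "JUNCTION"
BOTH = "BOTH"
UNKNOWN = "UNKNOWN"
CLAIMS = frozenset({DEPTH, JUNCTION, BOTH, UNKNOWN})

TRUTH = "TRUTH"
QUERY = "QUERY"


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A non-empty, 0-based half-open interval on a named contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True when ``other`` lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 across contigs).

    Half-open adjacency ([0,100) vs [100,200)) is zero overlap: two
    intervals must share at least one base to overlap.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 1.0 iff the spans are identical.

    This is the standard symmetric overlap fraction used to match
    structural variants; a threshold of >= 0.90 against a catalogued
    artifact defines a recurrent-artifact hit.
    """
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


@dataclass(frozen=True, slots=True)
class CnvEvent:
    """One deletion/duplication/insertion with dosage type and provenance.

    ``length`` is the reference span for DEL/DUP and the inserted-sequence
    length for INS (whose ``interval`` is the single reference base at the
    insertion point).  ``claim`` records the caller's evidence class;
    ``origin`` says which side of the comparison the event belongs to.
    """

    interval: GenomicInterval
    svtype: str
    length: int
    claim: str = UNKNOWN
    source_id: str = ""
    origin: str = QUERY

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.claim not in CLAIMS:
            raise ValueError(f"unknown claim {self.claim!r}")
        if self.origin not in (TRUTH, QUERY):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.length <= 0:
            raise ValueError("event length must be positive")
        if self.svtype in (DEL, DUP) and self.length != self.interval.length:
            raise ValueError(
                f"{self.svtype} length {self.length} != interval span "
                f"{self.interval.length}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class RegionSet:
    """A labelled collection of intervals indexed for overlap queries.

    Backed by one interval tree per contig; queries return exactly the
    member intervals sharing >= 1 base with the probe (equivalent to a
    linear scan).  Probes on contigs absent from the set return nothing.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = ""):
        self.label = label
        self.intervals: list[GenomicInterval] = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def overlapping(self, probe: GenomicInterval) -> list[GenomicInterval]:
        """All member intervals overlapping the probe by >= 1 bp."""
        tree = self._trees.get(probe.chrom)
        if tree is None:
            return []
        hits = [hit.data for hit in tree.overlap(probe.start, probe.end)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits

    def overlaps_any(self, probe: GenomicInterval) -> bool:
        tree = self._trees.get(probe.chrom)
        return tree is not None and bool(tree.overlap(probe.start, probe.end))

    def total_overlap_bp(self, probe: GenomicInterval) -> int:
        return sum(overlap_bp(probe, hit) for hit in self.overlapping(probe))


def build_region_index(
    intervals: Iterable[GenomicInterval], label: str = ""
) -> RegionSet:
    """Index intervals for overlap queries.  Duplicates are allowed."""
    return RegionSet(intervals, label=label)


def strip_chr_prefix(name: str) -> str:
    """Normalize 'chr1' -> '1'.

    GRCh37 resources mix UCSC-style ('chr1') and Ensembl-style ('1')
    contig names; readers accept a flag to apply this normalization so
    that contig matching stays an exact string comparison internally.
    """
    return name[3:] if name.lower().startswith("chr") and len(name) > 3 else name
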