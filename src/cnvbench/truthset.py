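"""Truth-set preparation: loading, insertion-to-duplication conversion,
and restriction to the evaluated event-size window.

Structural-variant truth sets commonly represent tandem duplications as
sequence-resolved insertions.  Because the benchmark matches on dosage
direction, such records must be reclassified before use: an insertion
whose sequence matches the adjacent reference (>= 95% identity, allowing
up to 2 bp of positional slop between the repeat copies) is accepted as a
duplication of that reference segment; insertions that fail verification
are excluded from the truth set.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from cnvbench.intervals import DUP, TRUTH, CnvEvent, GenomicInterval
from cnvbench.io import RawInsertion, SvVcfContent, read_sv_vcf

logger = logging.getLogger(__name__)

LEFT = "LEFT"
RIGHT = "RIGHT"

# Defaults for the evaluated event-size window, in bases.
MIN_EVENT_LEN = 500
MAX_EVENT_LEN = 10_000_000

ReferenceLike = Union[Mapping[str, str], "pyfaidx.Fasta"]  # noqa: F821


@dataclass(frozen=True)
class InsertionRecord:
    """A sequence-resolved insertion awaiting duplication verification."""

    chrom: str
    position: int  # 0-based point on the reference where the sequence inserts
    sequence: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("empty inserted sequence")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError("inserted sequence outside ACGTN alphabet")


@dataclass(frozen=True)
class DupVerification:
    """Outcome of matching an inserted sequence against its flanks."""

    identity: float
    offset: int
    flank: str
    accepted: bool
    reason: str = ""


def _ref_segment(reference: ReferenceLike, chrom: str, start: int, end: int) -> Optional[str]:
    """Extract reference bases [start, end); None when out of bounds."""
    if start < 0:
        return None
    try:
        seq = reference[chrom]
    except KeyError:
        return None
    if end > len(seq):
        return None
    return str(seq[start:end]).upper()


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def verify_duplication(
    rec: InsertionRecord,
    reference: ReferenceLike,
    identity_threshold: float = 0.95,
    slop: int = 2,
) -> tuple[DupVerification, Optional[CnvEvent]]:
    """Test whether an insertion is a tandem duplication of flanking sequence.

    For each flank (reference segment of the insertion's length ``L``
    starting at ``position + offset`` on the right, or ending at
    ``position + offset`` on the left) and each offset in ``[-slop, +slop]``,
    the ungapped identity (matching bases / L) is computed; the best
    (identity, offset, flank) combination is reported.  The insertion is
    accepted as a duplication iff the best identity reaches the threshold,
    in which case the emitted DUP event spans the matched reference
    segment (the duplicated footprint, which is what downstream exon
    matching needs).

    Identity is Hamming-style over the aligned window: the "slop" is
    realized as an integer positional offset scan, not a gapped alignment.
    Windows extending past a contig end are skipped for that flank/offset.
    """
    seq = rec.sequence.upper()
    if set(seq) <= {"N"}:
        return (
            DupVerification(0.0, 0, RIGHT, False, reason="n_only_sequence"),
            None,
        )
    n = len(seq)
    best: Optional[tuple[float, int, str, int, int]] = None
    # RIGHT before LEFT, small |offset| first: deterministic tie-breaking.
    for flank in (RIGHT, LEFT):
        for offset in sorted(range(-slop, slop + 1), key=abs):
            if flank == RIGHT:
                start = rec.position + offset
                end = start + n
            else:
                end = rec.position + offset
                start = end - n
            segment = _ref_segment(reference, rec.chrom, start, end)
            if segment is None or len(segment) != n:
                continue
            ident = _identity(seq, segment)
            if best is None or ident > best[0]:
                best = (ident, offset, flank, start, end)
    if best is None:
        return (
            DupVerification(0.0, 0, RIGHT, False, reason="no_reference_window"),
            None,
        )
    ident, offset, flank, start, end = best
    accepted = ident >= identity_threshold
    verdict = DupVerification(
        identity=ident,
        offset=offset,
        flank=flank,
        accepted=accepted,
        reason="" if accepted else "identity_below_threshold",
    )
    if not accepted:
        return verdict, None
    event = CnvEvent(
        interval=GenomicInterval(rec.chrom, start, end),
        svtype=DUP,
        length=end - start,
        source_id=rec.source_id,
        origin=TRUTH,
    )
    return verdict, event


def size_filter(
    events: Iterable[CnvEvent],
    min_len: int = MIN_EVENT_LEN,
    max_len: int = MAX_EVENT_LEN,
) -> list[CnvEvent]:
    """Keep events with ``min_len <= length <= max_len`` (both inclusive).

    Order-preserving and idempotent; dropped events are logged with the
    violated bound.
    """
    kept: list[CnvEvent] = []
    for ev in events:
        if ev.length < min_len:
            logger.info("size_filter dropped %s: length %d < %d", ev.source_id, ev.length, min_len)
        elif ev.length > max_len:
            logger.info("size_filter dropped %s: length %d > %d", ev.source_id, ev.length, max_len)
        else:
            kept.append(ev)
    return kept


def load_truth_vcf(
    path: str | os.PathLike,
    reference: Optional[ReferenceLike] = None,
    normalize_chrom: bool = False,
) -> SvVcfContent:
    """Load a truth VCF; DEL/DUP become events, INS records are collected
    for duplication verification, and parse failures carry reasons.

    When a reference is given, insertion records on contigs absent from it
    are moved to the error list.
    """
    content = read_sv_vcf(path, origin=TRUTH, normalize_chrom=normalize_chrom)
    if reference is not None:
        ok: list[RawInsertion] = []
        for ins in content.insertions:
            try:
                reference[ins.chrom]
            except KeyError:
                from cnvbench.io import SvParseError

                content.errors.append(
                    SvParseError(ins.source_id, f"contig {ins.chrom} absent from reference")
                )
                continue
            ok.append(ins)
        content.insertions = ok
    return content


@dataclass
class TruthSet:
    """A prepared truth set plus the insertion-verification audit trail."""

    events: list[CnvEvent]
    audit: pd.DataFrame  # one row per INS record: identity, offset, flank, decision
    errors: list  # SvParseError records from parsing
    contigs: dict[str, int]


def prepare_truth_set(
    path: str | os.PathLike,
    reference: ReferenceLike,
    identity_threshold: float = 0.95,
    slop: int = 2,
    min_len: int = MIN_EVENT_LEN,
    max_len: int = MAX_EVENT_LEN,
    normalize_chrom: bool = False,
) -> TruthSet:
    """End-to-end truth preparation: load, verify insertions, size-filter."""
    content = load_truth_vcf(path, reference, normalize_chrom=normalize_chrom)
    events = list(content.events)
    rows = []
    for raw in content.insertions:
        rec = InsertionRecord(raw.chrom, raw.position, raw.sequence, raw.source_id)
        verdict, event = verify_duplication(
            rec, reference, identity_threshold=identity_threshold, slop=slop
        )
        rows.append(
            {
                "source_id": rec.source_id,
                "identity": round(verdict.identity, 6),
                "offset": verdict.offset,
                "flank": verdict.flank,
                "decision": "DUP" if verdict.accepted else "excluded",
                "reason": verdict.reason,
            }
        )
        if event is not None:
            events.append(event)
    audit = pd.DataFrame(
        rows, columns=["source_id", "identity", "offset", "flank", "decision", "reason"]
    )
    events = size_filter(events, min_len=min_len, max_len=max_len)
    return TruthSet(events=events, audit=audit, errors=content.errors, contigs=content.contigs)
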