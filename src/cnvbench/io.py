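"""Readers and writers for the standard formats the toolkit consumes.

BED is 0-based half-open and passes straight into the internal
convention.  VCF POS is 1-based; pysam already exposes ``record.start``
as POS-1 and ``record.stop`` as the INFO END, which together give the
half-open reference span of a symbolic DEL/DUP record.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from cnvbench.intervals import (
    BOTH,
    CLAIMS,
    DEL,
    DEPTH,
    DUP,
    INS,
    JUNCTION,
    QUERY,
    TRUTH,
    UNKNOWN,
    CnvEvent,
    GenomicInterval,
    strip_chr_prefix,
)

logger = logging.getLogger(__name__)

# DRAGEN encodes the evidence class in INFO/SVCLAIM: D = depth,
# J = junction (breakpoint) only, DJ = both.
_SVCLAIM_MAP = {"D": DEPTH, "J": JUNCTION, "DJ": BOTH, "JD": BOTH}


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | os.PathLike, normalize_chrom: bool = False) -> list[GenomicInterval]:
    """Read BED3+ (extra columns ignored) into intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom = strip_chr_prefix(fields[0]) if normalize_chrom else fields[0]
            out.append(GenomicInterval(chrom, int(fields[1]), int(fields[2])))
    return out


def write_bed(
    path: str | os.PathLike,
    intervals: Iterable[GenomicInterval],
    names: Optional[Sequence[str]] = None,
) -> None:
    """Write BED3 (or BED4 when names are given)."""
    ivs = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                cols.append(names[i])
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# SV VCF


@dataclass
class SvParseError:
    source_id: str
    reason: str


@dataclass
class SvVcfContent:
    """Parsed structural-variant VCF: events plus per-record parse errors."""

    events: list[CnvEvent] = field(default_factory=list)
    insertions: list["RawInsertion"] = field(default_factory=list)
    errors: list[SvParseError] = field(default_factory=list)
    contigs: dict[str, int] = field(default_factory=dict)


@dataclass
class RawInsertion:
    """A sequence-resolved INS record before duplication verification."""

    chrom: str
    position: int  # 0-based insertion point on the reference
    sequence: str
    source_id: str


def _info_get(rec: pysam.VariantRecord, key: str):
    """INFO lookup tolerating keys missing from the header declaration."""
    try:
        value = rec.info.get(key)
    except ValueError:
        return None
    if isinstance(value, tuple):
        value = value[0]
    return value


def _record_svtype(rec: pysam.VariantRecord) -> Optional[str]:
    svtype = _info_get(rec, "SVTYPE")
    if svtype is None and rec.alts:
        alt = rec.alts[0]
        if alt.startswith("<") and alt.endswith(">"):
            svtype = alt.strip("<>").split(":")[0]
    return svtype


def _record_claim(rec: pysam.VariantRecord) -> str:
    raw = _info_get(rec, "SVCLAIM")
    if raw is None:
        return UNKNOWN
    claim = _SVCLAIM_MAP.get(str(raw).upper())
    if claim is None:
        logger.warning("unparseable SVCLAIM %r; treating as UNKNOWN", raw)
        return UNKNOWN
    return claim


def read_sv_vcf(
    path: str | os.PathLike,
    origin: str = QUERY,
    normalize_chrom: bool = False,
) -> SvVcfContent:
    """Parse DEL/DUP/INS records from a structural-variant VCF.

    DEL/DUP become :class:`CnvEvent`; sequence-resolved INS records are
    collected separately for duplication verification.  Records of other
    types, or records missing both END and SVLEN, are reported in
    ``errors`` rather than silently dropped.
    """
    content = SvVcfContent()
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for contig in vcf.header.contigs.values():
            name = strip_chr_prefix(contig.name) if normalize_chrom else contig.name
            content.contigs[name] = contig.length or 0
        for rec in vcf:
            rid = rec.id or f"{rec.chrom}:{rec.pos}"
            chrom = strip_chr_prefix(rec.chrom) if normalize_chrom else rec.chrom
            svtype = _record_svtype(rec)
            if svtype is None:
                content.errors.append(SvParseError(rid, "no SVTYPE or symbolic ALT"))
                continue
            if svtype == INS:
                seq = None
                if rec.alts and not rec.alts[0].startswith("<"):
                    alt = rec.alts[0]
                    ref = rec.ref or ""
                    # strip the shared padding base
                    seq = alt[len(ref):] if alt.startswith(ref) else alt
                if not seq:
                    seq = _info_get(rec, "SEQ")
                if not seq:
                    content.errors.append(
                        SvParseError(rid, "INS without sequence-resolved ALT")
                    )
                    continue
                content.insertions.append(
                    RawInsertion(chrom, rec.pos, str(seq).upper(), rid)
                )
                continue
            if svtype not in (DEL, DUP):
                content.errors.append(
                    SvParseError(rid, f"unsupported SVTYPE {svtype}")
                )
                continue
            start = rec.start
            svlen = _info_get(rec, "SVLEN")
            if svlen is not None:
                # SVLEN is authoritative when present: htslib reinterprets
                # spans of SVLEN-bearing symbolic records with a padding
                # base, so rec.stop cannot be trusted for them
                end = start + abs(int(svlen))
            else:
                end = rec.stop
                # without INFO END, pysam falls back to start + len(ref),
                # which is not a real span for a symbolic record
                if end is None or end - start <= len(rec.ref or "N"):
                    content.errors.append(
                        SvParseError(rid, "missing both END and SVLEN")
                    )
                    continue
            try:
                interval = GenomicInterval(chrom, start, end)
                event = CnvEvent(
                    interval=interval,
                    svtype=svtype,
                    length=interval.length,
                    claim=_record_claim(rec),
                    source_id=rid,
                    origin=origin,
                )
            except ValueError as exc:
                content.errors.append(SvParseError(rid, str(exc)))
                continue
            content.events.append(event)
    for err in content.errors:
        logger.info("skipped VCF record %s: %s", err.source_id, err.reason)
    return content


_FILTER_DESCRIPTIONS = {
    "SIZE_MIN": "Event shorter than the minimum evaluated length",
    "SIZE_MAX": "Event longer than the maximum evaluated length",
    "JUNCTION_LONG": "Junction-only call above the junction-only length cap",
    "GAP_OVERLAP": "Overlaps an assembly-gap (centromere/telomere) region",
    "RECURRENT_ARTIFACT": "Matches a recurrent artifact region",
}


def _sv_header(contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length if length else None)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SVLEN", 1, "Integer", "Length of the variant")
    header.info.add("SVCLAIM", 1, "String", "Evidence claim (D/J/DJ)")
    for tag, desc in _FILTER_DESCRIPTIONS.items():
        header.filters.add(tag, None, None, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("SAMPLE")
    return header


_CLAIM_TO_SVCLAIM = {DEPTH: "D", JUNCTION: "J", BOTH: "DJ"}


def write_sv_vcf(
    path: str | os.PathLike,
    events: Iterable[CnvEvent],
    contigs: Mapping[str, int],
    filters: Optional[Mapping[str, Sequence[str]]] = None,
) -> None:
    """Write DEL/DUP events as symbolic SV records with END and SVLEN.

    ``filters`` maps ``source_id`` to failed-rule tags; tagged records get
    those FILTER entries, everything else gets PASS.
    """
    header = _sv_header(contigs)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vcf:
        for i, ev in enumerate(sorted(events, key=lambda e: (e.chrom, e.interval.start))):
            rec = vcf.new_record(
                contig=ev.chrom,
                start=ev.interval.start,
                stop=ev.interval.end,
                alleles=("N", f"<{ev.svtype}>"),
                id=ev.source_id or f"event_{i}",
            )
            # SVLEN is deliberately not written: htslib rewrites the span of
            # SVLEN-bearing symbolic records with a padding-base convention,
            # which would shift END by one.  SVTYPE + END fully specify a
            # DEL/DUP span.
            rec.info["SVTYPE"] = ev.svtype
            if ev.claim in _CLAIM_TO_SVCLAIM:
                rec.info["SVCLAIM"] = _CLAIM_TO_SVCLAIM[ev.claim]
            tags = (filters or {}).get(ev.source_id, ())
            if tags:
                for tag in tags:
                    rec.filter.add(tag)
            else:
                rec.filter.add("PASS")
            rec.samples["SAMPLE"]["GT"] = (0, 1)
            vcf.write(rec)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(
    path: str | os.PathLike, sequences: Mapping[str, str], width: int = 60
) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a whole FASTA into memory (toy-scale references only)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
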