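"""Gene models, splice-padded coding exons, and synthetic gene spiking.

The benchmark's matching unit is the *padded exon*: a coding exon
extended by 15 bp of flanking intron so that splice-junction-disrupting
events are captured.  Sparse truth sets make exon overlaps rare, so this
module can also "spike" synthetic genes — translated copies of real gene
exon structures — into high-confidence regions (and directly on top of
truth duplications) to increase the number of scoreable overlaps.
Placement is coordinate-only: no sequence is synthesized.
"""

from __future__ import annotations

import itertools
import logging
import os
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from cnvbench.intervals import (
    CnvEvent,
    GenomicInterval,
    RegionSet,
    overlap_bp,
    strip_chr_prefix,
)

logger = logging.getLogger(__name__)

SPLICE_PAD = 15  # intronic bases added to each exon side


@dataclass(frozen=True)
class GeneModel:
    """A named transcript: strand plus ordered, non-overlapping coding exons."""

    name: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    synthetic: bool = False
    template_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.name} has no exons")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"gene {self.name}: exon on wrong contig")
            if ex.start < prev_end:
                raise ValueError(f"gene {self.name}: exons overlap or are unsorted")
            prev_end = ex.end

    @property
    def span(self) -> GenomicInterval:
        """First exon start to last exon end."""
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    def translated(self, chrom: str, new_start: int, name: str) -> "GeneModel":
        """An exact translation of this gene's exon structure to a new locus."""
        shift = new_start - self.exons[0].start
        return GeneModel(
            name=name,
            chrom=chrom,
            strand=self.strand,
            exons=tuple(GenomicInterval(chrom, e.start + shift, e.end + shift) for e in self.exons),
            synthetic=True,
            template_name=self.name,
        )


@dataclass(frozen=True)
class PaddedExon:
    """A coding exon extended by splice padding; the matching unit.

    ``key`` identifies the exon across data structures (gene names must be
    unique within one analysis).
    """

    interval: GenomicInterval
    gene: GeneModel
    exon_index: int

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene.name, self.exon_index)


def padded_exons(
    genes: Iterable[GeneModel],
    pad: int = SPLICE_PAD,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> list[PaddedExon]:
    """Extend each coding exon by ``pad`` bases on both sides.

    Padding is clipped at position 0 and, when contig lengths are known,
    at the contig end.  Padded exons of one gene may touch or overlap each
    other; they remain distinct match units.
    """
    out: list[PaddedExon] = []
    for gene in genes:
        limit = (contig_lengths or {}).get(gene.chrom)
        for i, exon in enumerate(gene.exons):
            start = max(0, exon.start - pad)
            end = exon.end + pad
            if limit is not None:
                end = min(end, limit)
            out.append(PaddedExon(GenomicInterval(gene.chrom, start, end), gene, i))
    return out


class ExonIndex:
    """Overlap index over padded exons (per-contig interval trees)."""

    def __init__(self, exons: Iterable[PaddedExon]):
        self.exons: list[PaddedExon] = list(exons)
        self._trees: dict[str, IntervalTree] = {}
        for pe in self.exons:
            self._trees.setdefault(pe.interval.chrom, IntervalTree()).addi(
                pe.interval.start, pe.interval.end, pe
            )

    def __len__(self) -> int:
        return len(self.exons)

    def overlapping(self, probe: GenomicInterval) -> list[PaddedExon]:
        tree = self._trees.get(probe.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(probe.start, probe.end)]
        hits.sort(key=lambda pe: (pe.interval.start, pe.gene.name, pe.exon_index))
        return hits


def build_exon_index(
    genes: Iterable[GeneModel],
    pad: int = SPLICE_PAD,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> ExonIndex:
    return ExonIndex(padded_exons(genes, pad=pad, contig_lengths=contig_lengths))


# ---------------------------------------------------------------------------
# Loading gene models


def _merge_exons(name: str, exons: list[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    exons = sorted(exons, key=lambda e: (e.start, e.end))
    merged: list[GenomicInterval] = []
    for ex in exons:
        if merged and ex.start < merged[-1].end:
            logger.warning("gene %s: merging overlapping exons", name)
            last = merged.pop()
            merged.append(GenomicInterval(ex.chrom, last.start, max(last.end, ex.end)))
        else:
            merged.append(ex)
    return tuple(merged)


def _parse_bed12_line(line: str, normalize_chrom: bool) -> GeneModel:
    f = line.split("\t")
    if len(f) < 12:
        raise ValueError(f"BED12 line has {len(f)} fields")
    chrom = strip_chr_prefix(f[0]) if normalize_chrom else f[0]
    chrom_start, chrom_end = int(f[1]), int(f[2])
    name, strand = f[3], f[5]
    n_blocks = int(f[9])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError(f"gene {name}: blockCount does not match block lists")
    exons = []
    for size, rel in zip(sizes, starts):
        s = chrom_start + rel
        e = s + size
        if e > chrom_end:
            raise ValueError(f"gene {name}: block end {e} exceeds chromEnd {chrom_end}")
        exons.append(GenomicInterval(chrom, s, e))
    return GeneModel(name=name, chrom=chrom, strand=strand, exons=_merge_exons(name, exons))


def _load_bed12(path: str | os.PathLike, normalize_chrom: bool) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    genes, rejects = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            try:
                genes.append(_parse_bed12_line(line, normalize_chrom))
            except ValueError as exc:
                rejects.append((f"line {ln}", str(exc)))
    return genes, rejects


def _load_gff3(path: str | os.PathLike, normalize_chrom: bool) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    """Group CDS features by transcript parent; exons stored in ascending order."""
    by_tx: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            parent = attrs.get("Parent") or attrs.get("ID") or "unknown"
            chrom = strip_chr_prefix(f[0]) if normalize_chrom else f[0]
            start, end = int(f[3]) - 1, int(f[4])  # GFF3 is 1-based inclusive
            entry = by_tx.setdefault(parent, {"chrom": chrom, "strand": f[6], "exons": []})
            entry["exons"].append(GenomicInterval(chrom, start, end))
    genes, rejects = [], []
    for name, entry in by_tx.items():
        try:
            genes.append(
                GeneModel(
                    name=name,
                    chrom=entry["chrom"],
                    strand=entry["strand"] if entry["strand"] in "+-" else "+",
                    exons=_merge_exons(name, entry["exons"]),
                )
            )
        except ValueError as exc:
            rejects.append((name, str(exc)))
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.name))
    return genes, rejects


def load_gene_models(
    path: str | os.PathLike,
    fmt: Optional[str] = None,
    normalize_chrom: bool = False,
) -> list[GeneModel]:
    """Load transcripts from BED12 (blocks = coding exons) or GFF3 (CDS).

    One model per transcript; canonical-transcript selection is the
    caller's responsibility upstream.  Malformed entries are logged and
    skipped, never silently coerced.
    """
    if fmt is None:
        name = str(path).lower()
        fmt = "gff3" if name.endswith((".gff", ".gff3")) else "bed12"
    if fmt == "bed12":
        genes, rejects = _load_bed12(path, normalize_chrom)
    elif fmt == "gff3":
        genes, rejects = _load_gff3(path, normalize_chrom)
    else:
        raise ValueError(f"unknown gene-model format {fmt!r}")
    for ident, reason in rejects:
        logger.warning("rejected gene model (%s): %s", ident, reason)
    return genes


def write_bed12(path: str | os.PathLike, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            sizes = ",".join(str(e.length) for e in g.exons)
            starts = ",".join(str(e.start - span.start) for e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(span.start),
                        str(span.end),
                        g.name,
                        "0",
                        g.strand,
                        str(span.start),
                        str(span.end),
                        "0,0,0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Synthetic gene spiking


@dataclass
class SpikeResult:
    genes: list[GeneModel]
    shortfall: int = 0  # placements requested but not achievable
    notes: list[str] = field(default_factory=list)


def _gene_span_tree(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        sp = g.span
        trees.setdefault(g.chrom, IntervalTree()).addi(sp.start, sp.end, g)
    return trees


def spike_synthetic_genes(
    templates: Sequence[GeneModel],
    high_conf: RegionSet,
    real_genes: Sequence[GeneModel] = (),
    truth_events: Sequence[CnvEvent] = (),
    min_gap: int = 100_000,
    n_target: Optional[int] = None,
    seed: int = 0,
    on_top_of: Optional[str] = None,
) -> SpikeResult:
    """Plant translated copies of template gene structures into the genome.

    General mode (``on_top_of is None``): each contig is scanned left to
    right; at each feasible anchor a template (drawn round-robin from a
    seed-shuffled cycle) is translated so that its gene span lies wholly
    inside one high-confidence region, overlaps no real gene span, and
    starts at least ``min_gap`` bases after the previous synthetic gene's
    end on that contig.  Placement stops at ``n_target`` (when given) or
    at exhaustion.

    On-top-of mode: for each truth event of svtype ``on_top_of``, a
    template is translated so at least one of its exons overlaps the
    event span, subject to the same containment and real-gene constraints
    but exempt from the min-gap rule (the anchor is dictated by the
    event).  These placements increase exon overlaps for sparse variant
    types such as duplications.

    An unreachable ``n_target`` yields a shortfall count, not an error.
    Same seed, same inputs => identical placements.
    """
    if not templates:
        raise ValueError("at least one template gene is required")
    rng = random.Random(seed)
    shuffled = list(templates)
    rng.shuffle(shuffled)
    cycle = itertools.cycle(shuffled)

    real_trees = _gene_span_tree(real_genes)
    placed: list[GeneModel] = []
    placed_trees: dict[str, IntervalTree] = {}
    counter = itertools.count(1)

    def conflicts(chrom: str, start: int, end: int) -> Optional[int]:
        """Earliest position clearing all overlapping gene spans, or None."""
        worst = None
        for trees in (real_trees, placed_trees):
            tree = trees.get(chrom)
            if tree is None:
                continue
            hits = tree.overlap(start, end)
            if hits:
                furthest = max(h.end for h in hits)
                worst = furthest if worst is None else max(worst, furthest)
        return worst

    def place(template: GeneModel, chrom: str, anchor: int) -> GeneModel:
        gene = template.translated(chrom, anchor, f"syn_{template.name}_{next(counter)}")
        placed.append(gene)
        sp = gene.span
        placed_trees.setdefault(chrom, IntervalTree()).addi(sp.start, sp.end, gene)
        return gene

    if on_top_of is None:
        regions_by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in sorted(high_conf, key=lambda iv: (iv.chrom, iv.start)):
            regions_by_chrom.setdefault(iv.chrom, []).append(iv)
        done = False
        for chrom in sorted(regions_by_chrom):
            if done:
                break
            prev_end: Optional[int] = None
            for region in regions_by_chrom[chrom]:
                cursor = region.start
                while True:
                    if n_target is not None and len(placed) >= n_target:
                        done = True
                        break
                    anchor = cursor
                    if prev_end is not None:
                        anchor = max(anchor, prev_end + min_gap)
                    template = next(cycle)
                    span_len = template.span.length
                    if anchor + span_len > region.end:
                        # re-queue the template so skipping a region does not
                        # consume a cycle slot
                        cycle = itertools.chain([template], cycle)
                        break
                    blocker = conflicts(chrom, anchor, anchor + span_len)
                    if blocker is not None:
                        cycle = itertools.chain([template], cycle)
                        cursor = blocker
                        continue
                    gene = place(template, chrom, anchor)
                    prev_end = gene.span.end
                    cursor = anchor
                if done:
                    break
        shortfall = 0 if n_target is None else max(0, n_target - len(placed))
        notes = [f"general-mode shortfall: {shortfall}"] if shortfall else []
        return SpikeResult(genes=placed, shortfall=shortfall, notes=notes)

    # --- on-top-of mode -----------------------------------------------------
    notes: list[str] = []
    events = [ev for ev in truth_events if ev.svtype == on_top_of]
    if n_target is not None:
        events = events[:n_target]
    missed = 0
    for ev in events:
        template = next(cycle)
        span = template.span
        chrom = ev.chrom
        candidate_anchors: list[int] = []
        for exon in template.exons:
            rel = exon.start - span.start
            rel_end = exon.end - span.start
            # exon start pinned to event start; exon end pinned to event end;
            # exon centred on the event
            candidate_anchors.append(ev.interval.start - rel)
            candidate_anchors.append(ev.interval.end - rel_end)
            mid_shift = (ev.interval.start + ev.interval.end) // 2 - (exon.start + exon.end) // 2
            candidate_anchors.append(span.start + mid_shift)
        placed_this = False
        for anchor in candidate_anchors:
            if anchor < 0:
                continue
            start, end = anchor, anchor + span.length
            within_hc = any(
                hc.start <= start and end <= hc.end
                for hc in high_conf.overlapping(GenomicInterval(chrom, max(start, 0), max(end, start + 1)))
            )
            if not within_hc:
                continue
            if conflicts(chrom, start, end) is not None:
                continue
            gene = place(template, chrom, anchor)
            if not any(overlap_bp(ex, ev.interval) > 0 for ex in gene.exons):
                # constraint violated (should not happen with pinned anchors)
                placed.pop()
                placed_trees[chrom].remove_overlap(start, end)
                continue
            placed_this = True
            break
        if not placed_this:
            missed += 1
            notes.append(f"no feasible on-top-of placement for event {ev.source_id or ev.interval}")
    return SpikeResult(genes=placed, shortfall=missed, notes=notes)


# ---------------------------------------------------------------------------
# Independent placement audit


def audit_spiked_genes(
    synthetic: Sequence[GeneModel],
    high_conf: Sequence[GenomicInterval],
    real_genes: Sequence[GeneModel],
    min_gap: int = 100_000,
    check_gap: bool = True,
) -> list[str]:
    """Brute-force check of placement constraints; returns violations.

    Deliberately avoids the interval indexes used for placement: every
    check is a linear scan, so it can serve as an independent oracle.
    ``check_gap=False`` for on-top-of placements (gap rule does not apply).
    """
    violations: list[str] = []
    for gene in synthetic:
        sp = gene.span
        if not any(
            hc.chrom == sp.chrom and hc.start <= sp.start and sp.end <= hc.end
            for hc in high_conf
        ):
            violations.append(f"{gene.name}: span not inside any high-confidence region")
        for real in real_genes:
            rs = real.span
            if rs.chrom == sp.chrom and min(rs.end, sp.end) > max(rs.start, sp.start):
                violations.append(f"{gene.name}: overlaps real gene {real.name}")
    if check_gap:
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in synthetic:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, genes in by_chrom.items():
            genes = sorted(genes, key=lambda g: g.span.start)
            for prev, nxt in zip(genes, genes[1:]):
                gap = nxt.span.start - prev.span.end
                if gap < min_gap:
                    violations.append(
                        f"{prev.name}->{nxt.name}: gap {gap} < {min_gap} on {chrom}"
                    )
    for gene in synthetic:
        if gene.template_name is None:
            violations.append(f"{gene.name}: missing template provenance")
    return violations
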