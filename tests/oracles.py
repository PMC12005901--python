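"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's indexed/incremental code paths:
classification is a triple loop over (query, truth, exon); identity
search enumerates the full flank x offset grid; clustering goes through
networkx connected components.
"""

from __future__ import annotations

import random

import networkx as nx

from cnvbench.intervals import CnvEvent, GenomicInterval, QUERY, TRUTH, DEL, DUP


def seg_overlap(chrom_a, a0, a1, chrom_b, b0, b1) -> int:
    if chrom_a != chrom_b:
        return 0
    return max(0, min(a1, b1) - max(a0, b0))


def brute_force_classify(queries, truths, padded):
    """Reference classification over all (query, truth, exon) triples.

    ``padded`` is a list of (key, chrom, start, end) tuples for in-scope
    padded exons.  Returns (query statuses, truth statuses) where truth
    status is 'detected', 'fn' or 'ignored'.
    """
    def exons_of(ev):
        return {
            key
            for key, chrom, s, e in padded
            if seg_overlap(ev.chrom, ev.interval.start, ev.interval.end, chrom, s, e) > 0
        }

    q_exons = [exons_of(q) for q in queries]
    t_exons = [exons_of(t) for t in truths]

    q_status = []
    for q, qe in zip(queries, q_exons):
        if not qe:
            q_status.append("ignored")
            continue
        hit = any(
            t.svtype == q.svtype and qe & te for t, te in zip(truths, t_exons)
        )
        q_status.append("tp" if hit else "fp")
    t_status = []
    for t, te in zip(truths, t_exons):
        if not te:
            t_status.append("ignored")
            continue
        hit = any(
            q.svtype == t.svtype and te & qe for q, qe in zip(queries, q_exons)
        )
        t_status.append("detected" if hit else "fn")
    return q_status, t_status


def grid_best_identity(sequence: str, ref: str, position: int, slop: int):
    """Exhaustive (flank x offset) search for the best ungapped identity."""
    n = len(sequence)
    best = -1.0
    for offset in range(-slop, slop + 1):
        for flank in ("RIGHT", "LEFT"):
            if flank == "RIGHT":
                start, end = position + offset, position + offset + n
            else:
                end = position + offset
                start = end - n
            if start < 0 or end > len(ref):
                continue
            seg = ref[start:end]
            ident = sum(a == b for a, b in zip(sequence, seg)) / n
            best = max(best, ident)
    return best


def cluster_by_components(callsets, min_recurrence, recip_threshold):
    """Recurrent-artifact discovery via an explicit pairwise graph.

    Returns a set of frozensets of member labels ('sample:id'), one per
    cluster meeting the recurrence threshold.
    """
    nodes = [
        (sample, ev) for sample, calls in callsets.items() for ev in calls
    ]
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = nodes[i][1], nodes[j][1]
            if a.svtype != b.svtype or a.chrom != b.chrom:
                continue
            ov = seg_overlap(
                a.chrom, a.interval.start, a.interval.end,
                b.chrom, b.interval.start, b.interval.end,
            )
            if ov and min(ov / a.interval.length, ov / b.interval.length) >= recip_threshold:
                g.add_edge(i, j)
    out = set()
    for comp in nx.connected_components(g):
        samples = {nodes[i][0] for i in comp}
        if len(samples) >= min_recurrence:
            out.add(frozenset(f"{nodes[i][0]}:{nodes[i][1].source_id}" for i in comp))
    return out


def random_classification_instance(rng: random.Random):
    """A random small instance: single-exon genes at random positions,
    random DEL/DUP events on both sides (<=50 events, <=200 exons)."""
    from cnvbench.genes import GeneModel

    chroms = ["cA", "cB"]
    n_exons = rng.randint(5, 200)
    genes = []
    for i in range(n_exons):
        chrom = rng.choice(chroms)
        start = rng.randint(0, 200_000)
        length = rng.randint(50, 300)
        genes.append(
            GeneModel(
                name=f"g{i}",
                chrom=chrom,
                strand="+",
                exons=(GenomicInterval(chrom, start, start + length),),
            )
        )

    def random_events(n, origin):
        events = []
        for i in range(n):
            chrom = rng.choice(chroms)
            start = rng.randint(0, 200_000)
            length = rng.randint(100, 20_000)
            svtype = rng.choice([DEL, DUP])
            events.append(
                CnvEvent(
                    GenomicInterval(chrom, start, start + length),
                    svtype,
                    length,
                    source_id=f"{origin[0].lower()}{i}",
                    origin=origin,
                )
            )
        return events

    n_q = rng.randint(1, 25)
    n_t = rng.randint(1, 25)
    return genes, random_events(n_q, QUERY), random_events(n_t, TRUTH)
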