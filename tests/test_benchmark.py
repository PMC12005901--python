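import math
import random

import pytest

from cnvbench.benchmark import (
    FN,
    FP,
    IGNORED,
    TP,
    adjust_multi_exon,
    classify,
    compute_metrics,
    default_strata,
)
from cnvbench.genes import GeneModel, build_exon_index, padded_exons
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
from oracles import brute_force_classify, random_classification_instance


def gene(name, chrom, exon_coords):
    return GeneModel(
        name=name,
        chrom=chrom,
        strand="+",
        exons=tuple(GenomicInterval(chrom, s, e) for s, e in exon_coords),
    )


def ev(start, end, svtype=DEL, origin=QUERY, sid="", chrom="c1"):
    return CnvEvent(
        GenomicInterval(chrom, start, end),
        svtype,
        end - start,
        source_id=sid or f"{origin[0]}{start}",
        origin=origin,
    )


@pytest.fixture
def ten_exon_gene_index():
    g = gene("G", "c1", [(i * 2_000, i * 2_000 + 150) for i in range(1, 11)])
    return g, build_exon_index([g])


def by_id(reports):
    return {r.event.source_id: r for r in reports}


class TestClassify:
    def test_shared_exon_same_type_is_tp(self, ten_exon_gene_index):
        """Query spanning exons 2-3 and truth spanning exon 3 match through
        the shared exon; both sides are detected."""
        g, index = ten_exon_gene_index
        query = ev(g.exons[1].start - 50, g.exons[2].end + 50, DEL, QUERY, "q")
        truth = ev(g.exons[2].start - 10, g.exons[2].end + 10, DEL, TRUTH, "t")
        rep = by_id(classify([query], [truth], index))
        assert rep["q"].status == TP
        assert rep["t"].status == TP
        assert {pe.key for pe in rep["q"].mediating_exons} == {("G", 2)}
        assert rep["q"].matched_ids == ["t"]

    def test_dosage_direction_mismatch_is_fp(self, ten_exon_gene_index):
        g, index = ten_exon_gene_index
        query = ev(g.exons[0].start, g.exons[0].end, DUP, QUERY, "q")
        truth = ev(g.exons[0].start, g.exons[0].end, DEL, TRUTH, "t")
        rep = by_id(classify([query], [truth], index))
        assert rep["q"].status == FP
        assert rep["t"].status == FN

    def test_intergenic_query_ignored(self, ten_exon_gene_index):
        g, index = ten_exon_gene_index
        query = ev(500_000, 510_000, DEL, QUERY, "q")
        (rep,) = classify([query], [], index)
        assert rep.status == IGNORED
        counts = adjust_multi_exon([rep])
        assert counts.precision is None and counts.ignored == 1

    def test_exonless_truth_excluded_from_denominator(self, ten_exon_gene_index):
        g, index = ten_exon_gene_index
        truth = ev(500_000, 505_000, DEL, TRUTH, "t")
        (rep,) = classify([], [truth], index)
        assert rep.status == IGNORED
        assert adjust_multi_exon([rep]).sensitivity is None

    def test_breakpoint_disagreement_tolerated(self, ten_exon_gene_index):
        """Matching is exon-mediated only: a query and truth sharing an exon
        match even when their intervals do not overlap each other."""
        g, index = ten_exon_gene_index
        # both touch exon 5's padded region but from opposite sides
        exon = g.exons[4]
        query = ev(exon.end - 10, exon.end + 3_000 - 160, DEL, QUERY, "q")
        truth = ev(exon.start - 500, exon.start + 10, DEL, TRUTH, "t")
        rep = by_id(classify([query], [truth], index))
        assert rep["q"].status == TP and rep["t"].status == TP

    def test_pad_captures_splice_region(self, ten_exon_gene_index):
        g, index = ten_exon_gene_index
        exon = g.exons[0]
        # event entirely intronic but within 15 bp of the exon boundary
        query = ev(exon.end + 5, exon.end + 300, DEL, QUERY, "q")
        (rep,) = classify([query], [], index)
        assert rep.status == FP  # overlaps the padded exon, no truth

    def test_restrict_to_panel_exons(self):
        on_panel = gene("panelG", "c1", [(1_000, 1_150)])
        off_panel = gene("otherG", "c1", [(50_000, 50_150)])
        index = build_exon_index([on_panel, off_panel])
        restrict = RegionSet([GenomicInterval("c1", 900, 1_300)], "panel")
        q_on = ev(900, 1_200, DEL, QUERY, "q_on")
        q_off = ev(49_900, 50_200, DEL, QUERY, "q_off")
        rep = by_id(classify([q_on, q_off], [], index, restrict_to=restrict))
        assert rep["q_on"].status == FP
        assert rep["q_off"].status == IGNORED  # only off-panel exon overlap

    def test_ins_rejected(self, ten_exon_gene_index):
        _, index = ten_exon_gene_index
        ins = CnvEvent(GenomicInterval("c1", 10, 11), INS, 500, origin=QUERY)
        with pytest.raises(ValueError, match="INS"):
            classify([ins], [], index)

    def test_input_order_invariance(self):
        rng = random.Random(99)
        genes, queries, truths = random_classification_instance(rng)
        index = build_exon_index(genes)
        base = {
            (r.event.source_id, r.event.origin): r.status
            for r in classify(queries, truths, index)
        }
        q2, t2 = list(queries), list(truths)
        rng.shuffle(q2)
        rng.shuffle(t2)
        shuffled = {
            (r.event.source_id, r.event.origin): r.status
            for r in classify(q2, t2, index)
        }
        assert base == shuffled

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        genes, queries, truths = random_classification_instance(rng)
        index = build_exon_index(genes)
        padded = [
            (pe.key, pe.interval.chrom, pe.interval.start, pe.interval.end)
            for pe in padded_exons(genes)
        ]
        exp_q, exp_t = brute_force_classify(queries, truths, padded)
        reports = classify(queries, truths, index)
        got_q = [r.status.lower() for r in reports if r.event.origin == QUERY]
        got_t = [
            {"TP": "detected", "FN": "fn", "IGNORED": "ignored"}[r.status]
            for r in reports
            if r.event.origin == TRUTH
        ]
        assert got_q == exp_q
        assert got_t == exp_t


class TestAdjustMultiExon:
    def test_multi_exon_event_counts_once(self, ten_exon_gene_index):
        g, index = ten_exon_gene_index
        span = ev(g.exons[0].start - 100, g.exons[-1].end + 100, DEL, QUERY, "q")
        truth = ev(g.exons[0].start - 100, g.exons[-1].end + 100, DEL, TRUTH, "t")
        counts = adjust_multi_exon(classify([span], [truth], index))
        assert (counts.tp_query, counts.tp_truth) == (1, 1)  # not 10

    def test_two_queries_one_truth(self, ten_exon_gene_index):
        """Distinct sub-calls each count on the query side; the truth event
        still counts once."""
        g, index = ten_exon_gene_index
        truth = ev(g.exons[0].start, g.exons[2].end, DEL, TRUTH, "t")
        q1 = ev(g.exons[0].start, g.exons[0].end, DEL, QUERY, "q1")
        q2 = ev(g.exons[2].start, g.exons[2].end, DEL, QUERY, "q2")
        counts = adjust_multi_exon(classify([q1, q2], [truth], index))
        assert (counts.tp_query, counts.tp_truth, counts.fn, counts.fp) == (2, 1, 0, 0)

    def test_one_query_matching_two_truths_counts_once(self, ten_exon_gene_index):
        g, index = ten_exon_gene_index
        t1 = ev(g.exons[0].start, g.exons[0].end, DEL, TRUTH, "t1")
        t2 = ev(g.exons[1].start, g.exons[1].end, DEL, TRUTH, "t2")
        q = ev(g.exons[0].start, g.exons[1].end, DEL, QUERY, "q")
        counts = adjust_multi_exon(classify([q], [t1, t2], index))
        assert (counts.tp_query, counts.tp_truth) == (1, 2)

    def test_zero_reports(self):
        counts = adjust_multi_exon([])
        assert (counts.tp_truth, counts.fn, counts.tp_query, counts.fp) == (0, 0, 0, 0)
        assert counts.sensitivity is None and counts.precision is None

    def test_counts_never_exceed_event_totals(self):
        for seed in range(10):
            rng = random.Random(1_000 + seed)
            genes, queries, truths = random_classification_instance(rng)
            index = build_exon_index(genes)
            counts = adjust_multi_exon(classify(queries, truths, index))
            assert counts.tp_query + counts.fp <= len(queries)
            assert counts.tp_truth + counts.fn <= len(truths)


class TestComputeMetrics:
    def test_rates_arithmetic_and_null_contract(self, ten_exon_gene_index):
        g, index = ten_exon_gene_index
        truths = [
            ev(g.exons[i].start, g.exons[i].end, DEL, TRUTH, f"t{i}") for i in range(4)
        ]
        queries = [
            ev(g.exons[i].start, g.exons[i].end, DEL, QUERY, f"q{i}") for i in range(3)
        ]
        table = compute_metrics(classify(queries, truths, index))
        overall = table.row("ALL", "ALL")
        assert overall["sensitivity"] == pytest.approx(0.75)
        assert overall["precision"] == pytest.approx(1.0)
        dup_row = table.row("SVTYPE", "DUP")
        assert dup_row["sensitivity"] is None  # no DUP events: null, not 0
        assert dup_row["precision"] is None

    def test_perfect_queries_give_unit_rates_everywhere(self):
        for seed in (0, 1, 2):
            rng = random.Random(seed)
            genes, _, truths = random_classification_instance(rng)
            index = build_exon_index(genes)
            queries = [
                CnvEvent(t.interval, t.svtype, t.length, source_id=f"q_{t.source_id}")
                for t in truths
            ]
            table = compute_metrics(classify(queries, truths, index))
            for _, row in table.frame.iterrows():
                if row.tp_truth + row.fn:
                    assert row.sensitivity == 1.0
                if row.tp_query + row.fp:
                    assert row.precision == 1.0

    def test_removing_fp_weakly_increases_precision(self):
        rng = random.Random(77)
        genes, queries, truths = random_classification_instance(rng)
        index = build_exon_index(genes)
        reports = classify(queries, truths, index)
        fp_ids = [r.event.source_id for r in reports if r.status == FP]
        if not fp_ids:
            pytest.skip("instance produced no FP")
        base = adjust_multi_exon(reports).precision
        pruned = [q for q in queries if q.source_id != fp_ids[0]]
        new = adjust_multi_exon(classify(pruned, truths, index)).precision
        assert new is None or base is None or new >= base

    def test_length_and_exon_bins(self, ten_exon_gene_index):
        g, index = ten_exon_gene_index
        # 700 bp over one exon; 12.2 kb over six exons
        q_small = ev(g.exons[0].end - 700, g.exons[0].end, DEL, QUERY, "qs")
        q_large = ev(g.exons[0].start, g.exons[5].end + 1_850, DEL, QUERY, "ql")
        table = compute_metrics(classify([q_small, q_large], [], index))
        assert table.row("LENGTH_BIN", "0.5-1kb")["fp"] == 1
        assert table.row("LENGTH_BIN", ">10kb")["fp"] == 1
        assert table.row("LENGTH_BIN", ">=5kb")["fp"] == 1
        assert table.row("EXON_COUNT_BIN", "1")["fp"] == 1
        assert table.row("EXON_COUNT_BIN", ">5")["fp"] == 1
        assert table.row("EXON_COUNT_BIN", "2-5")["fp"] == 0
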