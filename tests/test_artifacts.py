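import random

import pytest

from cnvbench.artifacts import (
    ArtifactRegion,
    FilterConfig,
    GAP_OVERLAP,
    JUNCTION_LONG,
    RECIPROCAL_MODE,
    RECURRENT_ARTIFACT,
    SIZE_MAX,
    SIZE_MIN,
    TWO_BED_MODE,
    apply_filters,
    build_blacklist,
    read_blacklist_beds,
    write_blacklist_beds,
)
from cnvbench.fixtures import make_artifact_cohort
from cnvbench.intervals import (
    BOTH,
    DEL,
    DEPTH,
    DUP,
    JUNCTION,
    UNKNOWN,
    CnvEvent,
    GenomicInterval,
    RegionSet,
)
from oracles import cluster_by_components


def call(start, end, svtype=DEL, claim=UNKNOWN, sid="", chrom="c1"):
    return CnvEvent(
        GenomicInterval(chrom, start, end),
        svtype,
        end - start,
        claim=claim,
        source_id=sid or f"{svtype}_{start}_{end}",
    )


def artifact(start, end, svtype=DEL, chrom="c1"):
    iv = GenomicInterval(chrom, start, end)
    return ArtifactRegion(interval=iv, svtype=svtype, recurrence=3, member_ids=())


class TestApplyFilters:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (499, [SIZE_MIN]),
            (500, []),
            (10_000_000, []),
            (10_000_001, [SIZE_MAX]),
        ],
    )
    def test_size_boundaries(self, length, expected):
        (v,) = apply_filters([call(0, length)], FilterConfig())
        assert v.failed_rules == expected
        assert v.kept == (not expected)

    @pytest.mark.parametrize(
        "claim,expected_kept",
        [(JUNCTION, False), (DEPTH, True), (BOTH, True), (UNKNOWN, True)],
    )
    def test_junction_only_rule_above_1mb(self, claim, expected_kept):
        """A 2 Mb junction-only call is an artifact; with depth support (or
        no claim annotation at all) it is kept."""
        (v,) = apply_filters([call(0, 2_000_000, DUP, claim)], FilterConfig())
        assert v.kept is expected_kept
        if not expected_kept:
            assert v.failed_rules == [JUNCTION_LONG]

    def test_junction_only_below_cap_kept(self):
        (v,) = apply_filters([call(0, 900_000, DUP, JUNCTION)], FilterConfig())
        assert v.kept

    def test_gap_overlap_single_base(self):
        gaps = RegionSet([GenomicInterval("c1", 10_000, 20_000)], "gap")
        config = FilterConfig(gap_regions=gaps)
        hit, miss = apply_filters(
            [call(5_000, 10_001), call(4_000, 10_000)], config  # 1 bp in / adjacent
        )
        assert hit.failed_rules == [GAP_OVERLAP]
        assert miss.kept

    @pytest.mark.parametrize(
        "call_len,expected_kept",
        [
            (10_870, False),  # reciprocal overlap 10000/10870 = 0.920
            (11_236, True),  # 0.890
        ],
    )
    def test_reciprocal_artifact_thresholds(self, call_len, expected_kept):
        config = FilterConfig(artifact_regions=[artifact(0, 10_000)])
        (v,) = apply_filters([call(0, call_len)], config)
        assert v.kept is expected_kept
        if not expected_kept:
            assert v.failed_rules == [RECURRENT_ARTIFACT]

    def test_exact_090_boundary_is_mode_dependent(self):
        """Reciprocal overlap exactly 0.90 drops the call in direct mode;
        the two-BED containment surrogate keeps it because the call is not
        contained by the cluster's maximum interval."""
        art = artifact(0, 9_000)
        c = call(0, 10_000)  # recip = 9000/10000 = 0.90
        (direct,) = apply_filters([c], FilterConfig(artifact_regions=[art]))
        assert direct.failed_rules == [RECURRENT_ARTIFACT]
        (two_bed,) = apply_filters(
            [c], FilterConfig(artifact_regions=[art], artifact_mode=TWO_BED_MODE)
        )
        assert two_bed.kept

    def test_identical_call_dropped_in_both_modes(self):
        art = artifact(50_000, 60_000)
        c = call(50_000, 60_000)
        for mode in (RECIPROCAL_MODE, TWO_BED_MODE):
            (v,) = apply_filters(
                [c], FilterConfig(artifact_regions=[art], artifact_mode=mode)
            )
            assert v.failed_rules == [RECURRENT_ARTIFACT]

    def test_artifact_matching_is_svtype_aware(self):
        config = FilterConfig(artifact_regions=[artifact(0, 10_000, svtype=DEL)])
        (v,) = apply_filters([call(0, 10_000, DUP)], config)
        assert v.kept

    def test_all_failed_rules_reported(self):
        gaps = RegionSet([GenomicInterval("c1", 0, 100)], "gap")
        config = FilterConfig(gap_regions=gaps)
        (v,) = apply_filters([call(0, 499, DEL)], config)
        assert v.failed_rules == [SIZE_MIN, GAP_OVERLAP]

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            FilterConfig(min_len=0)
        with pytest.raises(ValueError):
            FilterConfig(junction_only_max_len=20_000_000)
        with pytest.raises(ValueError):
            FilterConfig(recip_threshold=0.0)
        with pytest.raises(ValueError):
            FilterConfig(artifact_mode="bogus")

    def test_subset_idempotence_and_independence(self):
        rng = random.Random(8)
        gaps = RegionSet(
            [GenomicInterval("c1", s, s + 5_000) for s in range(0, 500_000, 50_000)],
            "gap",
        )
        arts = [artifact(s, s + rng.randint(600, 20_000)) for s in range(0, 300_000, 30_000)]
        config = FilterConfig(gap_regions=gaps, artifact_regions=arts)
        calls = []
        for i in range(60):
            s = rng.randint(0, 600_000)
            calls.append(
                call(
                    s,
                    s + rng.randint(100, 2_000_000),
                    rng.choice([DEL, DUP]),
                    rng.choice([DEPTH, JUNCTION, UNKNOWN]),
                    sid=f"r{i}",
                )
            )
        verdicts = apply_filters(calls, config)
        kept = [v.event for v in verdicts if v.kept]
        assert set(kept) <= set(calls)
        again = apply_filters(kept, config)
        assert [v.event for v in again if v.kept] == kept  # idempotent
        # per-call independence: verdicts unchanged after removing another call
        reduced = apply_filters(calls[1:], config)
        assert [(v.event.source_id, v.failed_rules) for v in reduced] == [
            (v.event.source_id, v.failed_rules) for v in verdicts[1:]
        ]


class TestBuildBlacklist:
    def test_identical_call_across_all_samples(self):
        iv = (100_000, 150_000)
        callsets = {
            f"s{i}": [call(*iv, sid=f"s{i}_a")] for i in range(5)
        }
        (region,) = build_blacklist(callsets, min_recurrence=3)
        assert region.recurrence == 5
        assert region.interval == GenomicInterval("c1", *iv)
        assert region.min_interval == region.max_interval == region.interval

    def test_private_call_never_blacklisted(self):
        callsets = {
            "s1": [call(0, 10_000, sid="a")],
            "s2": [call(500_000, 510_000, sid="b")],
        }
        assert build_blacklist(callsets, min_recurrence=2) == []

    def test_chain_cluster_min_max_beds(self, tmp_path):
        """Three staggered calls pairwise above 0.90 form one cluster whose
        min interval is their intersection and max interval their union."""
        callsets = {
            "s1": [call(0, 10_000, sid="a")],
            "s2": [call(400, 10_400, sid="b")],
            "s3": [call(800, 10_800, sid="c")],
        }
        (region,) = build_blacklist(callsets, min_recurrence=3)
        assert region.min_interval == GenomicInterval("c1", 800, 10_000)
        assert region.max_interval == GenomicInterval("c1", 0, 10_800)
        assert region.interval == GenomicInterval("c1", 400, 10_400)  # medians
        min_bed, max_bed = tmp_path / "min.bed", tmp_path / "max.bed"
        write_blacklist_beds([region], min_bed, max_bed)
        (loaded,) = read_blacklist_beds(min_bed, max_bed)
        assert loaded.min_interval == region.min_interval
        assert loaded.max_interval == region.max_interval
        assert loaded.svtype == DEL and loaded.recurrence == 3

    def test_a_blacklisted_call_is_always_refiltered(self):
        cohort = make_artifact_cohort(3)
        regions = build_blacklist(cohort.callsets, min_recurrence=2)
        config = FilterConfig(artifact_regions=regions)
        # every cluster member must be dropped when refiltered
        members = [
            c
            for calls in cohort.callsets.values()
            for c in calls
            if "shared" in c.source_id
        ]
        verdicts = apply_filters(members, config)
        assert all(RECURRENT_ARTIFACT in v.failed_rules for v in verdicts)

    def test_sample_order_permutation_invariance(self):
        cohort = make_artifact_cohort(21, n_samples=4)
        items = list(cohort.callsets.items())
        a = build_blacklist(dict(items), min_recurrence=2)
        b = build_blacklist(dict(reversed(items)), min_recurrence=2)
        assert a == b

    def test_min_recurrence_above_sample_count(self):
        cohort = make_artifact_cohort(5, n_samples=3)
        assert build_blacklist(cohort.callsets, min_recurrence=9) == []

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            build_blacklist({"only": [call(0, 1_000)]})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_connected_components_oracle(self, seed):
        rng = random.Random(seed)
        chrom = "cX"
        callsets = {}
        for si in range(rng.randint(2, 5)):
            calls = []
            for ci in range(rng.randint(1, 8)):
                start = rng.randint(0, 60_000)
                length = rng.randint(600, 12_000)
                calls.append(
                    call(
                        start,
                        start + length,
                        rng.choice([DEL, DUP]),
                        sid=f"s{si}c{ci}",
                        chrom=chrom,
                    )
                )
            callsets[f"s{si}"] = calls
        min_rec = rng.randint(2, 3)
        regions = build_blacklist(callsets, min_recurrence=min_rec)
        got = {frozenset(r.member_ids) for r in regions}
        expected = cluster_by_components(callsets, min_rec, 0.90)
        assert got == expected
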