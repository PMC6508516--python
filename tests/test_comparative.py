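"""Contamination filter, five-way presence/absence partition, filter
accounting, and candidate selection semantics."""

import numpy as np
import pytest

from rhizocomp.comparative import (VennPartition, contamination_filter,
                                   partition_accounting, select_candidates,
                                   venn_partition)
from rhizocomp.seqio import HomologyHit


def hit(q, s, bits=100.0, ev=1e-40):
    return HomologyHit(q, s, 100.0, 50, 0, 0, 1, 150, 1, 50, ev, bits)


PLANTS = {"Sorghum bicolor", "Thinopyrum intermedium", "Sorghum halepense"}


class TestContaminationFilter:
    def test_nonplant_top_hit_removed(self):
        hits = [hit("q1", "fus1")]
        kept, removed = contamination_filter(
            ["q1"], hits, PLANTS, {"fus1": "Fusarium oxysporum"})
        assert removed == {"q1"}

    def test_plant_top_hit_kept(self):
        hits = [hit("q1", "sb1")]
        kept, removed = contamination_filter(
            ["q1"], hits, PLANTS, {"sb1": "Sorghum bicolor"})
        assert kept == {"q1"}

    def test_no_hits_kept(self):
        kept, removed = contamination_filter(["q1"], [], PLANTS, {})
        assert kept == {"q1"} and removed == set()

    def test_top_hit_decides_not_any_hit(self):
        # stronger plant hit outranks a weaker non-plant one
        hits = [hit("q1", "sb1", bits=90.0), hit("q1", "fus1", bits=50.0)]
        taxa = {"sb1": "Sorghum bicolor", "fus1": "Fusarium oxysporum"}
        kept, _ = contamination_filter(["q1"], hits, PLANTS, taxa)
        assert kept == {"q1"}

    def test_empty_whitelist_raises(self):
        with pytest.raises(ValueError):
            contamination_filter(["q1"], [], set(), {})


class TestVennPartition:
    def test_toy_four_way(self):
        queries = ["qb", "qa", "qr", "qn"]
        annual = [hit("qb", "sb1"), hit("qa", "sb2")]
        rhiz = [hit("qb", "th1"), hit("qr", "th2")]
        part = venn_partition(queries, annual, rhiz,
                              rhizome_expressed_subjects=set())
        assert part.both == {"qb"}
        assert part.only_annual == {"qa"}
        assert part.only_rhiz_not_in_rhizome_assembly == {"qr"}
        assert part.only_rhiz_in_rhizome_assembly == frozenset()
        assert part.none == {"qn"}

    def test_rhizome_expressed_subject_routes_to_supported_category(self):
        part = venn_partition(["q1"], [], [hit("q1", "th1")],
                              rhizome_expressed_subjects={"th1"})
        assert part.only_rhiz_in_rhizome_assembly == {"q1"}

    def test_match_mode_top_vs_any(self):
        # top hit th1 is not rhizome-expressed; a weaker hit th2 is
        rhiz = [hit("q1", "th1", bits=90.0), hit("q1", "th2", bits=50.0)]
        top = venn_partition(["q1"], [], rhiz, {"th2"}, match_mode="top")
        any_ = venn_partition(["q1"], [], rhiz, {"th2"}, match_mode="any")
        assert top.only_rhiz_not_in_rhizome_assembly == {"q1"}
        assert any_.only_rhiz_in_rhizome_assembly == {"q1"}

    def test_unknown_query_in_hits_raises(self):
        with pytest.raises(ValueError, match="unknown query"):
            venn_partition(["q1"], [hit("ghost", "sb1")], [], set())

    def test_random_instances_match_set_oracle(self):
        rng = np.random.default_rng(21)
        queries = [f"q{i}" for i in range(200)]
        subjects_a = [f"sa{i}" for i in range(20)]
        subjects_r = [f"sr{i}" for i in range(20)]
        expressed = set(rng.choice(subjects_r, size=8, replace=False))
        annual, rhiz = [], []
        for q in queries:
            if rng.random() < 0.5:
                annual.append(hit(q, str(rng.choice(subjects_a))))
            for _ in range(int(rng.integers(0, 3))):
                rhiz.append(hit(q, str(rng.choice(subjects_r)),
                                bits=float(rng.integers(40, 200))))
        part = venn_partition(queries, annual, rhiz, expressed, "top")
        # independent oracle: direct set membership recomputation
        a_ids = {h.query_id for h in annual}
        r_ids = {h.query_id for h in rhiz}
        tops = {}
        for h in sorted(rhiz, key=lambda h: (-h.bitscore, h.evalue, h.subject_id)):
            tops.setdefault(h.query_id, h.subject_id)
        assert part.both == a_ids & r_ids
        assert part.only_annual == a_ids - r_ids
        only_r = r_ids - a_ids
        assert part.only_rhiz_in_rhizome_assembly == {
            q for q in only_r if tops[q] in expressed}
        assert part.only_rhiz_not_in_rhizome_assembly == {
            q for q in only_r if tops[q] not in expressed}
        assert part.none == set(queries) - a_ids - r_ids
        part.validate()


class TestPartitionAccounting:
    COUNTS = {
        "both": 90_038,
        "only_annual": 15_327,
        "only_rhiz_not_in_rhizome_assembly": 732,
        "only_rhiz_in_rhizome_assembly": 259,
        "none": 34_820,
    }

    def test_total_from_category_counts(self):
        report = partition_accounting(self.COUNTS)
        assert report["total"] == 141_176

    def test_annual_marginal(self):
        assert partition_accounting(self.COUNTS)["with_annual_hit"] == 105_365

    def test_rhizomatous_marginal(self):
        assert partition_accounting(self.COUNTS)["with_rhizomatous_hit"] == 91_029

    def test_only_rhizomatous_total(self):
        assert partition_accounting(self.COUNTS)["only_rhizomatous"] == 991

    def test_overlapping_partition_raises(self):
        bad = VennPartition(
            both=frozenset({"q1"}), only_annual=frozenset({"q1"}),
            only_rhiz_not_in_rhizome_assembly=frozenset(),
            only_rhiz_in_rhizome_assembly=frozenset(), none=frozenset())
        with pytest.raises(ValueError, match="overlap"):
            partition_accounting(bad)

    def test_negative_count_raises(self):
        bad = dict(self.COUNTS, both=-1)
        with pytest.raises(ValueError):
            partition_accounting(bad)


def toy_partition(pool):
    return VennPartition(
        both=frozenset(), only_annual=frozenset(),
        only_rhiz_not_in_rhizome_assembly=frozenset(),
        only_rhiz_in_rhizome_assembly=frozenset(pool),
        none=frozenset())


class TestSelectCandidates:
    def test_filters_intersect(self):
        part = toy_partition({"a", "b", "c"})
        fpkm = {"a": 5.0, "b": 0.5, "c": 5.0}
        kept = {"a", "b"}  # c flagged as contaminant
        cs = select_candidates(part, fpkm, kept, min_fpkm=1.0)
        assert cs.candidate_ids == {"a"}

    def test_shared_subject_collapses(self):
        part = toy_partition({"a", "b"})
        cs = select_candidates(part, {"a": 5.0, "b": 5.0}, {"a", "b"},
                               rhiz_top_subject={"a": "th1", "b": "th1"})
        assert cs.candidate_ids == {"a", "b"}
        assert cs.unique_subjects == {"th1"}

    def test_monotone_in_threshold_and_whitelist(self):
        part = toy_partition({"a", "b", "c"})
        fpkm = {"a": 0.5, "b": 2.0, "c": 10.0}
        lo = select_candidates(part, fpkm, {"a", "b", "c"}, min_fpkm=0.1)
        hi = select_candidates(part, fpkm, {"a", "b", "c"}, min_fpkm=5.0)
        assert hi.candidate_ids <= lo.candidate_ids
        shrunk = select_candidates(part, fpkm, {"b"}, min_fpkm=0.1)
        assert shrunk.candidate_ids <= lo.candidate_ids

    def test_candidates_within_pool(self):
        part = toy_partition({"a"})
        cs = select_candidates(part, {"a": 5.0, "z": 5.0}, {"a", "z"})
        assert cs.candidate_ids <= part.only_rhiz_in_rhizome_assembly

    def test_missing_fpkm_treated_as_unexpressed(self):
        part = toy_partition({"a"})
        cs = select_candidates(part, {}, {"a"}, min_fpkm=1.0)
        assert cs.candidate_ids == frozenset()
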