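import numpy as np
import pytest

from xwaspipe.metrics import (
    compare_replication_times,
    enumerate_mmrp,
    gene_qtl_profiles,
    replication_matrix,
)
from xwaspipe.types import EvidenceLine, NoveltyCall, QtlType, SupportCount


def line(dataset="SCZ_2022", qtl="eQTL", tool="FUSION", gene="G1", source="SG"):
    return EvidenceLine(
        gwas_dataset=dataset, qtl_type=qtl, tissue_group="brain", tool=tool,
        gene_symbol=gene, source_group=source,
    )


def call(gene, novel, disorder="SCZ"):
    return NoveltyCall(
        gene_symbol=gene, disorder=disorder, window=("1", 1, 2),
        min_p=1e-3 if novel else 1e-12, n_snps_in_window=1, is_novel=novel,
    )


def support(gene, n, disorder="SCZ"):
    lines = frozenset(line(dataset=f"SCZ_{2000+i}", gene=gene) for i in range(n))
    return SupportCount(gene_symbol=gene, disorder=disorder, count=n, lines=lines)


class TestReplicationMatrix:
    def test_hand_counts(self):
        rm = replication_matrix({"A": {"g1", "g2"}, "B": {"g2"}})
        assert rm.ratios.loc["A", "B"] == pytest.approx(0.5)
        assert rm.ratios.loc["B", "A"] == pytest.approx(1.0)
        assert rm.counts.loc["A", "B"] == 1

    def test_identical_sets_unit_ratios(self):
        rm = replication_matrix({"A": {"g1"}, "B": {"g1"}})
        assert rm.ratios.loc["A", "B"] == 1.0 and rm.ratios.loc["B", "A"] == 1.0

    def test_disjoint_sets_zero_ratios(self):
        rm = replication_matrix({"A": {"g1"}, "B": {"g2"}})
        assert rm.ratios.loc["A", "B"] == 0.0 and rm.ratios.loc["B", "A"] == 0.0

    def test_empty_set_gives_missing_not_error(self):
        rm = replication_matrix({"A": set(), "B": {"g1"}})
        assert np.isnan(rm.ratios.loc["A", "B"])
        assert rm.ratios.loc["B", "B"] == 1.0

    def test_ratio_times_size_is_overlap_count(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(30)]
        for _ in range(25):
            sets = {
                lab: set(rng.choice(universe, size=rng.integers(1, 20), replace=False))
                for lab in "AB"
            }
            rm = replication_matrix(sets)
            for a in "AB":
                for b in "AB":
                    prod = rm.ratios.loc[a, b] * len(sets[a])
                    assert prod == pytest.approx(rm.counts.loc[a, b])


class TestReplicationTimes:
    def test_hand_medians(self):
        counts = [support("n1", 2), support("n2", 2), support("o1", 5), support("o2", 7)]
        calls = [call("n1", True), call("n2", True), call("o1", False), call("o2", False)]
        cmp = compare_replication_times(counts, calls)
        assert cmp.median_novel == 2 and cmp.median_non_novel == 6
        assert cmp.test_p is not None

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(2, 10, 40)
        counts = [support(f"g{i}", int(v)) for i, v in enumerate(vals)]
        calls = [call(f"g{i}", bool(i % 2)) for i in range(40)]
        cmp = compare_replication_times(counts, calls)
        assert cmp.test_p > 0.05

    def test_single_element_groups_flagged_degenerate(self):
        counts = [support("a", 2), support("b", 5)]
        calls = [call("a", True), call("b", False)]
        cmp = compare_replication_times(counts, calls)
        assert cmp.degenerate is True
        assert cmp.median_novel == 2 and cmp.median_non_novel == 5

    def test_empty_group_missing_p(self):
        counts = [support("a", 2)]
        calls = [call("a", True)]
        cmp = compare_replication_times(counts, calls)
        assert cmp.test_p is None and cmp.median_non_novel is None


class TestProfiles:
    def test_set_union_over_lines(self):
        lines = {line(qtl="eQTL"), line(qtl="sQTL")}
        profiles = gene_qtl_profiles(lines, "SCZ")
        assert profiles["G1"] == {QtlType.EQTL, QtlType.SQTL}

    def test_same_type_different_tools_dedups(self):
        lines = {line(tool="FUSION"), line(tool="SMR")}
        assert gene_qtl_profiles(lines, "SCZ")["G1"] == {QtlType.EQTL}

    def test_disorders_scoped_independently(self):
        lines = {line(dataset="SCZ_2022", qtl="eQTL"), line(dataset="BP_2021", qtl="sQTL")}
        assert gene_qtl_profiles(lines, "SCZ")["G1"] == {QtlType.EQTL}
        assert gene_qtl_profiles(lines, "BP")["G1"] == {QtlType.SQTL}


class TestMmrp:
    def test_hand_enumeration(self):
        profiles = {
            "g1": {QtlType.EQTL, QtlType.SQTL},
            "g2": {QtlType.EQTL, QtlType.SQTL},
            "g3": {QtlType.EQTL},
        }
        patterns = enumerate_mmrp(profiles, "SCZ")
        assert len(patterns) == 1
        assert patterns[0].genes == ["g1", "g2"]
        assert patterns[0].contains_eqtl is True

    def test_four_layer_profile_single_pattern(self):
        profiles = {"g1": {QtlType.EQTL, QtlType.SQTL, QtlType.PQTL, QtlType.MQTL}}
        patterns = enumerate_mmrp(profiles)
        assert len(patterns) == 1 and len(patterns[0].qtl_set) == 4

    def test_no_eqtl_pattern_flagged(self):
        profiles = {"g1": {QtlType.MQTL, QtlType.M6AQTL}}
        assert enumerate_mmrp(profiles)[0].contains_eqtl is False

    def test_restriction_can_empty_output(self):
        profiles = {"g1": {QtlType.EQTL, QtlType.SQTL}}
        assert enumerate_mmrp(profiles, restrict_to={"other"}) == []

    def test_partition_property_random_profiles(self):
        rng = np.random.default_rng(5)
        layers = list(QtlType)
        profiles = {
            f"g{i}": {layers[j] for j in rng.choice(5, rng.integers(1, 5), replace=False)}
            for i in range(60)
        }
        patterns = enumerate_mmrp(profiles)
        multi = {g for g, q in profiles.items() if len(q) >= 2}
        assert sum(len(p.genes) for p in patterns) == len(multi)
        covered = set().union(*[set(p.genes) for p in patterns]) if patterns else set()
        assert covered == multi

    def test_invariant_to_duplicate_lines(self):
        l1 = {line(qtl="eQTL"), line(qtl="sQTL")}
        l2 = l1 | {line(qtl="eQTL", tool="SMR")}  # adds duplicate type evidence
        p1 = enumerate_mmrp(gene_qtl_profiles(l1, "SCZ"), "SCZ")
        p2 = enumerate_mmrp(gene_qtl_profiles(l2, "SCZ"), "SCZ")
        assert [(p.qtl_set, p.genes) for p in p1] == [(p.qtl_set, p.genes) for p in p2]
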