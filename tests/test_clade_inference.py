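from itertools import combinations

import numpy as np
import pytest

from paleogene.clade_inference import (
    CladeRuleConfig,
    Status,
    assign_clade_status,
    date_all_genes,
    estimate_emergence,
    find_candidate_nodes,
    status_table,
)
from paleogene.synthetic import simulate_tree
from paleogene.timetree import enumerate_clades, read_timetree

from conftest import BALANCED4, presence_frame


def brute_force_candidates(tree, presence_row):
    """Independent oracle: statuses by direct counting, then a full node scan."""

    def status(leaves):
        detected = sum(bool(presence_row[sp]) for sp in leaves)
        if detected / len(leaves) > 0.8:
            return "existent"
        if (len(leaves) - detected) / len(leaves) > 0.8:
            return "absent"
        return "unknown"

    found = []
    for node in tree.nodes():
        if node.is_leaf:
            continue
        for a, b in combinations(node.children, 2):
            pair = {status(a.leaf_names()), status(b.leaf_names())}
            if pair == {"existent", "absent"}:
                found.append((node.id, node.age))
                break
    return sorted(found, key=lambda item: -item[1])


class TestAssignCladeStatus:
    @pytest.mark.parametrize(
        "detected,size,expected",
        [
            (5, 5, Status.EXISTENT),  # 100% > 80%
            (4, 5, Status.UNKNOWN),  # neither fraction strictly exceeds 0.8
            (1, 6, Status.ABSENT),  # undetected 5/6 > 0.8
            (0, 1, Status.ABSENT),
            (1, 1, Status.EXISTENT),
        ],
    )
    def test_forced_cases(self, detected, size, expected):
        assert assign_clade_status(detected, size) is expected

    def test_exhaustive_against_fraction_arithmetic(self):
        cfg = CladeRuleConfig()
        for size in range(1, 33):
            for detected in range(size + 1):
                got = assign_clade_status(detected, size, cfg)
                if detected / size > 0.8:
                    assert got is Status.EXISTENT
                elif (size - detected) / size > 0.8:
                    assert got is Status.ABSENT
                else:
                    assert got is Status.UNKNOWN

    def test_small_clades_need_unanimity(self):
        # at sizes <= 5 with the 0.8 rule, existent needs all detected and
        # absent needs zero detected (4/5 = 0.8 is not strictly greater)
        for size in range(1, 6):
            for detected in range(size + 1):
                got = assign_clade_status(detected, size)
                assert (got is Status.EXISTENT) == (detected == size)
                assert (got is Status.ABSENT) == (detected == 0)

    @pytest.mark.parametrize("fraction", [0.5, 0.6, 0.8, 0.95])
    def test_statuses_mutually_exclusive(self, fraction):
        cfg = CladeRuleConfig(fraction)
        for size in range(1, 20):
            for detected in range(size + 1):
                got = assign_clade_status(detected, size, cfg)
                existent = detected / size > fraction
                absent = (size - detected) / size > fraction
                assert not (existent and absent)
                assert got is not Status.EXISTENT or existent
                assert got is not Status.ABSENT or absent

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            CladeRuleConfig(0.4)
        with pytest.raises(ValueError):
            CladeRuleConfig(1.0)


class TestStatusTable:
    def test_ubiquitous_gene_existent_everywhere(self, balanced4):
        presence = presence_frame(balanced4, {"g": {"A", "B", "C", "D"}})
        table = status_table(presence, enumerate_clades(balanced4))
        assert all(s is Status.EXISTENT for s in table.statuses.loc["g"])

    def test_missing_gene_absent_everywhere(self, balanced4):
        presence = presence_frame(balanced4, {"g": set()})
        table = status_table(presence, enumerate_clades(balanced4))
        assert all(s is Status.ABSENT for s in table.statuses.loc["g"])

    def test_single_leaf_detection_on_large_tree(self, primate_tree_32):
        presence = presence_frame(primate_tree_32, {"g": {"Homo_sapiens"}})
        clades = enumerate_clades(primate_tree_32)
        table = status_table(presence, clades)
        for clade in clades:
            got = table.status("g", clade.node_id)
            if "Homo_sapiens" not in clade.leaves:
                assert got is Status.ABSENT
            elif clade.size == 1:
                assert got is Status.EXISTENT
            else:
                # detected fraction 1/size <= 1/2; status hinges on the
                # undetected fraction (size-1)/size vs the 0.8 rule
                expect = (
                    Status.ABSENT
                    if (clade.size - 1) / clade.size > 0.8
                    else Status.UNKNOWN
                )
                assert got is expect

    def test_missing_taxon_named_in_error(self, balanced4):
        presence = presence_frame(balanced4, {"g": {"A"}}).drop(columns=["D"])
        with pytest.raises(KeyError, match="D"):
            status_table(presence, enumerate_clades(balanced4))


class TestFindCandidateNodes:
    def _statuses(self, tree, detections):
        presence = presence_frame(tree, {"g": detections})
        return status_table(presence, enumerate_clades(tree)).gene_statuses("g")

    def test_contrast_at_root_only(self, balanced4):
        statuses = self._statuses(balanced4, {"A", "B"})
        cands = find_candidate_nodes(balanced4, statuses)
        assert [age for _, age in cands] == [pytest.approx(3.0)]

    def test_no_contrast_when_everywhere(self, balanced4):
        statuses = self._statuses(balanced4, {"A", "B", "C", "D"})
        assert find_candidate_nodes(balanced4, statuses) == []

    def test_regain_pattern_keeps_all_contrasts(self, balanced4):
        # presence in two disjoint cherries' single leaves: reversible
        # (Wagner-style) patterns yield a candidate at each cherry, with no
        # single-origin suppression
        statuses = self._statuses(balanced4, {"A", "C"})
        cands = find_candidate_nodes(balanced4, statuses)
        assert len(cands) == 2
        assert all(age == pytest.approx(1.0) for _, age in cands)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(
            n_leaves=int(rng.integers(4, 11)), root_age=30.0, seed=seed + 100
        )
        species = tree.leaf_names()
        row = {sp: bool(rng.random() < 0.4) for sp in species}
        presence = presence_frame(tree, {"g": {s for s, v in row.items() if v}})
        statuses = status_table(
            presence, enumerate_clades(tree)
        ).gene_statuses("g")
        got = find_candidate_nodes(tree, statuses)
        expected = brute_force_candidates(tree, row)
        assert [(n, pytest.approx(a)) for n, a in expected] == got


class TestEstimateEmergence:
    def test_earliest_candidate_wins(self):
        est = estimate_emergence(
            "g", [(7, 2.1), (3, 6.4)], Status.UNKNOWN, True
        )
        assert est.category == "dated"
        assert est.age == pytest.approx(6.4)
        assert est.candidate_ages == [pytest.approx(6.4), pytest.approx(2.1)]

    def test_pre_root_when_existent_at_root(self):
        est = estimate_emergence("g", [], Status.EXISTENT, True)
        assert est.category == "pre_root"

    def test_undetected_when_nowhere(self):
        est = estimate_emergence("g", [], Status.ABSENT, False)
        assert est.category == "undetected"

    def test_no_signal_otherwise(self):
        est = estimate_emergence("g", [], Status.UNKNOWN, True)
        assert est.category == "no_signal"

    def test_equal_age_tie_breaks_to_first_clade_key(self, balanced4):
        presence = presence_frame(balanced4, {"g": {"A", "C"}})
        ests = date_all_genes(balanced4, presence)
        (est,) = ests
        # both cherries are candidates at age 1; the A-containing cherry has
        # the smaller clade ordering key
        assert est.age == pytest.approx(1.0)
        node = next(n for n in balanced4.nodes() if n.id == est.node_id)
        assert node.leaf_names() == {"A", "B"}


class TestDateAllGenes:
    def test_hand_fixture_on_balanced_tree(self, balanced4):
        presence = presence_frame(
            balanced4,
            {"g_ab": {"A", "B"}, "g_a": {"A"}, "g_all": {"A", "B", "C", "D"}},
        )
        by_gene = {e.gene: e for e in date_all_genes(balanced4, presence)}
        assert by_gene["g_ab"].category == "dated"
        assert by_gene["g_ab"].age == pytest.approx(3.0)  # the root
        assert by_gene["g_a"].category == "dated"
        assert by_gene["g_a"].age == pytest.approx(1.0)  # parent of A
        assert by_gene["g_all"].category == "pre_root"

    def test_all_detected_means_all_pre_root(self, primate_tree_32):
        species = set(primate_tree_32.leaf_names())
        presence = presence_frame(
            primate_tree_32, {f"g{i}": species for i in range(3)}
        )
        assert all(
            e.category == "pre_root"
            for e in date_all_genes(primate_tree_32, presence)
        )

    def test_dated_age_dominates_all_candidates(self, primate_tree_32):
        rng = np.random.default_rng(11)
        species = primate_tree_32.leaf_names()
        detections = {
            f"g{i}": {sp for sp in species if rng.random() < 0.3}
            for i in range(20)
        }
        presence = presence_frame(primate_tree_32, detections)
        for est in date_all_genes(primate_tree_32, presence):
            if est.category == "dated":
                assert est.age == max(est.candidate_ages)
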