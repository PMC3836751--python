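"""Distances, neighbor joining, rooting, masking, and paralogue pruning."""

import math

import dendropy
import numpy as np
import pytest

from seedcoal.genetrees import (RootingError, SaturationError,
                                SubtreeFilterRules, best_single_copy_clade,
                                jc_distance, monophyly_mask,
                                neighbor_joining, paralogue_prune,
                                root_with_outgroup, subtree_filter)
from seedcoal.trees import (parse_newick, rooted_species_clades,
                            species_bipartitions, split_label, same_topology)

from conftest import random_paralog_tree


class TestJCDistance:
    def test_identical_rows_zero(self):
        assert jc_distance(["ACGT", "ACGT"])[0, 1] == 0.0

    def test_closed_form_at_p_ten_percent(self):
        rows = ["A" * 90 + "C" * 10, "A" * 100]
        assert jc_distance(rows)[0, 1] == pytest.approx(0.107326, abs=1e-6)

    def test_saturated_pair_raises(self):
        with pytest.raises(SaturationError, match="saturated"):
            jc_distance(["AAAA", "CCCC"])

    def test_no_comparable_columns_raises(self):
        with pytest.raises(ValueError, match="no comparable"):
            jc_distance(["AA--", "--AA"])

    def test_gapped_columns_excluded(self):
        # only 2 comparable columns, 1 mismatch
        rows = ["AC-T", "AT-T"]
        p = 1 / 3
        expect = -0.75 * math.log(1 - 4 * p / 3)
        assert jc_distance(rows)[0, 1] == pytest.approx(expect)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = neighbor_joining(["A", "B", "C"], d)
        lens = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lens == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_additive_four_taxon_distances_recover_split(self):
        # tree ((A:1,B:1):1,(C:1,D:1))
        d = np.array([[0, 2, 3, 3], [2, 0, 3, 3],
                      [3, 3, 0, 2], [3, 3, 2, 0]], float)
        t = neighbor_joining(list("ABCD"), d)
        assert species_bipartitions(t) == {frozenset({"C", "D"})}

    def test_tie_broken_by_smallest_pair(self):
        # fully symmetric distances: every Q equal; A,B must join first
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        t = neighbor_joining(list("ABCD"), d)
        assert frozenset({"C", "D"}) in species_bipartitions(t)

    def test_invalid_distances_rejected(self):
        d = np.array([[0, -1.0], [-1.0, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(["A", "B", "C"],
                             np.array([[0, 1, np.nan], [1, 0, 1],
                                       [np.nan, 1, 0]]))
        with pytest.raises(ValueError):
            neighbor_joining(["A", "B"], d)

    def test_additive_distances_recover_random_topologies(self):
        """NJ on exactly additive distances reproduces the generating
        topology; cross-checked against scikit-bio's NJ."""
        import io
        from skbio import DistanceMatrix, TreeNode
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        for rep in range(10):
            tree = random_paralog_tree(rng)  # random rooted tree, >=3 tips
            labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
            if len(labels) < 4:
                continue
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in pdm.taxon_iter()}
            n = len(labels)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]],
                                                     taxa[labels[j]])
            mine = neighbor_joining(labels, d)
            assert species_bipartitions(mine, sep="\0") == \
                species_bipartitions(tree, sep="\0")
            ref = skbio_nj(DistanceMatrix(d, ids=labels))
            ref_dp = parse_newick(str(ref).strip())
            assert species_bipartitions(ref_dp, sep="\0") == \
                species_bipartitions(mine, sep="\0")


class TestRooting:
    def test_outgroup_rooting(self):
        t = parse_newick("(A|1,B|1,(C|1,out|1));", rooted=False)
        r = root_with_outgroup(t, "out")
        assert frozenset({"A", "B", "C"}) in rooted_species_clades(r)

    def test_missing_outgroup_raises(self):
        t = parse_newick("(A|1,B|1,C|1);")
        with pytest.raises(RootingError, match="absent"):
            root_with_outgroup(t, "out")

    def test_outgroup_cherry_rooting(self):
        t = parse_newick("(A|1,B|1,(out|1,out|2));", rooted=False)
        r = root_with_outgroup(t, "out")
        assert frozenset({"out"}) in rooted_species_clades(r)
        assert frozenset({"A", "B"}) in rooted_species_clades(r)

    def test_non_separable_outgroup_warns(self):
        t = parse_newick("((out|1,A|1),(out|2,B|1),C|1);")
        with pytest.warns(UserWarning, match="not separable"):
            root_with_outgroup(t, "out")


class TestMonophylyMask:
    def test_same_species_cherry_collapsed_to_longest(self):
        t = parse_newick("((a|1:1,a|2:2):1,b|1:1);", rooted=True)
        m = monophyly_mask(t, lengths={"1": 50, "2": 80})
        assert sorted(lf.taxon.label for lf in m.leaf_node_iter()) == \
            ["a|2", "b|1"]
        kept = next(lf for lf in m.leaf_node_iter()
                    if lf.taxon.label == "a|2")
        assert kept.edge.length == 2.0  # original tip length retained

    def test_no_same_species_clade_unchanged(self):
        t = parse_newick("((a|1,b|1),(a|2,b|2));", rooted=True)
        m = monophyly_mask(t)
        assert sorted(lf.taxon.label for lf in m.leaf_node_iter()) == \
            ["a|1", "a|2", "b|1", "b|2"]

    def test_maximal_clade_collapsed_once(self):
        t = parse_newick("(((a|1,a|2),a|3),b|1);", rooted=True)
        m = monophyly_mask(t, lengths={"1": 10, "2": 30, "3": 20})
        assert sorted(lf.taxon.label for lf in m.leaf_node_iter()) == \
            ["a|2", "b|1"]

    def test_tie_goes_to_smallest_sequence_id(self):
        t = parse_newick("((a|2,a|1),b|1);", rooted=True)
        m = monophyly_mask(t, lengths={"1": 10, "2": 10})
        assert "a|1" in [lf.taxon.label for lf in m.leaf_node_iter()]

    def test_idempotent(self, ):
        t = parse_newick("(((a|1,a|2),b|1),(b|2,c|1));", rooted=True)
        once = monophyly_mask(t)
        twice = monophyly_mask(once)
        assert sorted(lf.taxon.label for lf in once.leaf_node_iter()) == \
            sorted(lf.taxon.label for lf in twice.leaf_node_iter())


def _brute_force_best_clade(tree, sep="|"):
    """Independent scan: maximise (species, tips, -preorder) over clades
    holding at most one tip per species."""
    best = None
    for idx, node in enumerate(tree.preorder_node_iter()):
        species = [split_label(lf.taxon.label, sep)[0]
                   for lf in node.leaf_iter()]
        if len(species) != len(set(species)):
            continue
        key = (len(set(species)), len(species), -idx)
        if best is None or key > best[0]:
            best = (key, frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return best[1]


class TestParaloguePrune:
    def test_worked_example(self):
        t = parse_newick("((a|1,b|1),(a|2,(b|2,c|1)));", rooted=True)
        subs = paralogue_prune(t)
        got = [frozenset(lf.taxon.label for lf in s.leaf_node_iter())
               for s in subs]
        assert got == [frozenset({"a|2", "b|2", "c|1"}),
                       frozenset({"a|1", "b|1"})]

    def test_single_copy_tree_returned_unchanged(self):
        t = parse_newick("((a|1,b|1),c|1);", rooted=True)
        subs = paralogue_prune(t)
        assert len(subs) == 1
        assert same_topology(subs[0], t)

    def test_two_tips_same_species_yields_nothing(self):
        t = parse_newick("(a|1,a|2);", rooted=True)
        assert paralogue_prune(t) == []

    def test_outputs_single_copy_and_tip_disjoint(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            tree = random_paralog_tree(rng)
            subs = paralogue_prune(tree)
            seen = set()
            for s in subs:
                species = [split_label(lf.taxon.label)[0]
                           for lf in s.leaf_node_iter()]
                assert len(species) == len(set(species))
                labels = {lf.taxon.label for lf in s.leaf_node_iter()}
                assert not labels & seen
                seen |= labels

    def test_first_subtree_matches_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            tree = random_paralog_tree(rng)
            best = best_single_copy_clade(tree)
            expect = _brute_force_best_clade(tree)
            got = frozenset(lf.taxon.label for lf in best.leaf_iter())
            assert got == expect


class TestSubtreeFilter:
    rules = SubtreeFilterRules()

    def _tree(self, n_species):
        labels = [f"s{i:02d}|x" for i in range(n_species)]
        newick = "(" * (n_species - 1) + labels[0]
        for lb in labels[1:]:
            newick += f",{lb})"
        return parse_newick(newick + ";", rooted=True)

    def test_meets_both_thresholds(self):
        t = self._tree(7)
        assert subtree_filter([t], self.rules, set(range(10))) == [t]

    def test_fails_fraction_threshold(self):
        t = self._tree(7)
        assert subtree_filter([t], self.rules, set(range(12))) == []

    def test_fails_absolute_threshold(self):
        t = self._tree(6)
        assert subtree_filter([t], self.rules, set(range(8))) == []
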