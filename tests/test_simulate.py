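"""Multispecies-coalescent simulator, sequence evolution, fixture dataset."""

import json
import math
import os

import numpy as np
import pytest

from seedcoal.genetrees import p_distance, paralogue_prune
from seedcoal.simulate import (MSCModel, SeqSimConfig, inject_paralogs,
                               make_fixture_dataset, make_species_tree,
                               simulate_msc_gene_trees, simulate_sequences)
from seedcoal.trees import (parse_newick, rooted_species_clades, split_label)


def _three_taxon_concordance(t_internal: float, n_genes: int,
                             seed: int) -> float:
    sp = parse_newick(f"((A:{t_internal},B:{t_internal}):{t_internal},"
                      f"C:{2 * t_internal});", rooted=True)
    trees = simulate_msc_gene_trees(MSCModel(sp), n_genes, seed=seed)
    hits = sum(1 for t in trees
               if frozenset({"A", "B"}) in rooted_species_clades(t))
    return hits / n_genes


class TestMSCGeneTrees:
    def test_zero_internal_branch_is_uniform_over_resolutions(self):
        sp = parse_newick("((A:1,B:0.0001):0.0001,C:1);", rooted=True)
        trees = simulate_msc_gene_trees(MSCModel(sp), 6000, seed=1)
        counts = {"AB": 0, "AC": 0, "BC": 0}
        for t in trees:
            clades = rooted_species_clades(t)
            for pair in counts:
                if frozenset(pair) in clades:
                    counts[pair] += 1
        for n in counts.values():
            assert n / 6000 == pytest.approx(1 / 3, abs=0.03)

    def test_concordance_matches_closed_form_at_unit_branch(self):
        obs = _three_taxon_concordance(1.0, 8000, seed=2)
        expect = 1 - (2 / 3) * math.exp(-1.0)
        assert obs == pytest.approx(expect, abs=3 * math.sqrt(
            expect * (1 - expect) / 8000))

    def test_long_branch_concordance_near_one(self):
        assert _three_taxon_concordance(10.0, 1000, seed=3) > 0.999

    def test_deterministic_given_seed(self):
        sp = make_species_tree(6, "out", seed=4)
        a = simulate_msc_gene_trees(MSCModel(sp), 5, seed=5)
        b = simulate_msc_gene_trees(MSCModel(sp), 5, seed=5)
        from seedcoal.trees import to_newick
        assert [to_newick(t) for t in a] == [to_newick(t) for t in b]

    def test_matches_msprime_oracle(self):
        """Cross-check 3-taxon gene-tree concordance against msprime."""
        import msprime

        t_int = 1.0
        demography = msprime.Demography()
        # ploidy 1 with population size 1: one coalescent unit per generation
        for name in ("A", "B", "C", "AB", "ABC"):
            demography.add_population(name=name, initial_size=1.0)
        demography.add_population_split(time=t_int, derived=["A", "B"],
                                        ancestral="AB")
        demography.add_population_split(time=2 * t_int, derived=["AB", "C"],
                                        ancestral="ABC")
        n = 4000
        hits = 0
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1, "C": 1}, demography=demography,
            ploidy=1, num_replicates=n, random_seed=17)
        for ts in reps:
            tree = ts.first()
            a, b = 0, 1  # samples 0=A, 1=B, 2=C
            hits += tree.mrca(a, b) != tree.root
        oracle = hits / n
        mine = _three_taxon_concordance(t_int, 4000, seed=6)
        se = math.sqrt(2 * 0.25 / 4000)
        assert mine == pytest.approx(oracle, abs=4 * se)


class TestSimulateSequences:
    def test_jc_pairwise_divergence_closed_form(self):
        t = parse_newick("(A:0.05,B:0.05);", rooted=True)
        aln = simulate_sequences(t, SeqSimConfig(length=100000, seed=7))
        p = p_distance([aln["A"], aln["B"]])[0, 1]
        assert p == pytest.approx(0.75 * (1 - math.exp(-4 * 0.1 / 3)),
                                  abs=0.004)

    def test_zero_rate_copies_root(self):
        t = parse_newick("((A:1,B:1):1,C:2);", rooted=True)
        aln = simulate_sequences(t, SeqSimConfig(length=500, seed=8,
                                                 rate_multiplier=0.0))
        assert aln["A"] == aln["B"] == aln["C"]

    def test_extreme_rate_saturates_at_three_quarters(self):
        t = parse_newick("(A:1,B:1);", rooted=True)
        aln = simulate_sequences(t, SeqSimConfig(length=20000, seed=9,
                                                 rate_multiplier=20.0))
        p = p_distance([aln["A"], aln["B"]])[0, 1]
        assert p == pytest.approx(0.75, abs=0.01)

    def test_hky_reaches_stationary_composition(self):
        freqs = (0.4, 0.3, 0.2, 0.1)
        t = parse_newick("(A:8,B:8);", rooted=True)
        cfg = SeqSimConfig(model="HKY", kappa=4.0, base_freqs=freqs,
                           length=30000, seed=10)
        aln = simulate_sequences(t, cfg)
        row = aln["A"]
        for base, f in zip("ACGT", freqs):
            assert row.count(base) / len(row) == pytest.approx(f, abs=0.02)

    def test_missing_branch_length_rejected(self):
        t = parse_newick("(A,B);", rooted=True)
        with pytest.raises(ValueError, match="branch lengths"):
            simulate_sequences(t, SeqSimConfig(length=10, seed=0))


class TestInjectParalogs:
    def test_zero_probability_is_identity(self):
        t = parse_newick("((A|A_0:1,B|B_0:1):1,C|C_0:2);", rooted=True)
        out = inject_paralogs(t, 0.0, seed=1)
        assert sorted(lf.taxon.label for lf in out.leaf_node_iter()) == \
            ["A|A_0", "B|B_0", "C|C_0"]

    def test_certain_duplication_doubles_tips(self):
        t = parse_newick("((A|A_0:1,B|B_0:1):1,C|C_0:2);", rooted=True)
        out = inject_paralogs(t, 1.0, seed=2)
        labels = sorted(lf.taxon.label for lf in out.leaf_node_iter())
        assert len(labels) == 6
        species = [split_label(lb)[0] for lb in labels]
        assert all(species.count(sp) == 2 for sp in "ABC")

    def test_pruning_injected_tree_keeps_all_species(self):
        """After monophyly masking (a recent duplicate is a same-species
        cherry), pruning recovers one subtree spanning every species."""
        from seedcoal.genetrees import monophyly_mask
        sp = make_species_tree(6, "out", seed=3)
        gt = simulate_msc_gene_trees(MSCModel(sp), 1, seed=4)[0]
        dup = inject_paralogs(gt, 0.5, seed=5)
        subs = paralogue_prune(monophyly_mask(dup))
        best = subs[0]
        species = {split_label(lf.taxon.label)[0]
                   for lf in best.leaf_node_iter()}
        assert species == {split_label(lf.taxon.label)[0]
                           for lf in gt.leaf_node_iter()}


class TestFixtureDataset:
    def test_byte_identical_for_fixed_seed(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_fixture_dataset(str(d1), n_species=6, n_genes=4, seed=5)
        make_fixture_dataset(str(d2), n_species=6, n_genes=4, seed=5)
        for rel in ("manifest.json", "hits.tsv", "true_species_tree.nwk",
                    os.path.join("cds", "out.fna")):
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_no_missing_species_when_fraction_zero(self, tmp_path):
        ds = make_fixture_dataset(str(tmp_path / "c"), n_species=6,
                                  n_genes=4, missing_frac=0.0, p_dup=0.0,
                                  seed=6)
        for gid, members in ds.gene_families.items():
            species = {m.split("|")[0] for m in members}
            assert species == set(ds.species)

    def test_manifest_records_ground_truth(self, fixture_dataset):
        man = json.loads(
            (os.path.join(fixture_dataset.out_dir, "manifest.json")
             and open(os.path.join(fixture_dataset.out_dir,
                                   "manifest.json")).read()))
        assert man["outgroup"] == "out"
        assert len(man["genes"]) == man["n_genes"]
        truth = parse_newick(man["true_species_tree"], rooted=True)
        assert sorted(lf.taxon.label for lf in truth.leaf_node_iter()) == \
            fixture_dataset.species

    def test_cds_translates_to_protein(self, fixture_dataset):
        from Bio.Seq import Seq
        sid, prot = next(iter(fixture_dataset.proteins.items()))
        assert str(Seq(fixture_dataset.cds[sid]).translate()) == prot
        assert "*" not in prot
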