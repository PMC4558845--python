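import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytonuc.core_io import (CYTOSOLIC, EUKARYOTE, MITOCHONDRIAL, PROKARYOTE,
                             GeneticCode)
from cytonuc import simulate as sim
from cytonuc.substitution import AminoAcidModel, K80Model


class TestChildSeed:
    def test_deterministic_and_bounded(self):
        assert sim.child_seed(7, 3) == sim.child_seed(7, 3)
        assert 0 <= sim.child_seed(7, 3) < 2**31

    def test_distinct_indices_differ(self):
        seeds = {sim.child_seed(0, i) for i in range(100)}
        assert len(seeds) == 100


class TestFamilyTree:
    def test_annotations_complete(self):
        tree = sim.simulate_family_tree(seed=1)
        tips = tree.tip_labels()
        assert len(tips) == 14
        assert sum(tree.domain[t] == EUKARYOTE for t in tips) == 8
        assert sum(tree.domain[t] == PROKARYOTE for t in tips) == 6
        lin = [tree.lineage[t] for t in tips if t in tree.lineage]
        assert lin.count(MITOCHONDRIAL) == 4 and lin.count(CYTOSOLIC) == 4

    def test_lineages_are_clades(self):
        tree = sim.simulate_family_tree(seed=2)
        mt = {t for t in tree.tip_labels()
              if tree.lineage.get(t) == MITOCHONDRIAL}
        assert any(set(tree.subtended_tips(e)) == mt for e in tree.edges())

    def test_deterministic(self):
        a = sim.simulate_family_tree(seed=3).to_newick()
        b = sim.simulate_family_tree(seed=3).to_newick()
        assert a == b
        assert a != sim.simulate_family_tree(seed=4).to_newick()

    def test_positive_branch_lengths(self):
        tree = sim.simulate_family_tree(seed=5)
        assert all(tree.length[e] > 0 for e in tree.edges())


class TestSimulateAlignment:
    def test_shape_and_alphabet(self, wag, family):
        aln, tree = family
        assert aln.n_columns == 150
        assert sorted(aln.ids) == sorted(tree.tip_labels())
        assert all(set(r.residues) <= set("ARNDCQEGHILKMFPSTWYV")
                   for r in aln.records)

    def test_deterministic(self, wag):
        tree = sim.simulate_family_tree(seed=6)
        a = sim.simulate_alignment(tree, wag, 50, seed=7)
        b = sim.simulate_alignment(tree, wag, 50, seed=7)
        assert [r.residues for r in a.records] == [r.residues for r in b.records]

    def test_recovers_generating_divergence(self, wag):
        from cytonuc.core_io import Phylogeny
        from cytonuc.substitution import wag_ml_distance
        tree = Phylogeny.from_newick("(a:0.2,b:0.2);")
        aln = sim.simulate_alignment(tree, wag, 5000, seed=8)
        d = wag_ml_distance(aln.row("a").residues, aln.row("b").residues, wag)
        assert d.distance == pytest.approx(0.4, abs=0.05)

    def test_nucleotide_model(self):
        from cytonuc.core_io import Phylogeny
        tree = Phylogeny.from_newick("(a:0.1,b:0.1);")
        aln = sim.simulate_alignment(tree, K80Model(2.0), 100, seed=9)
        assert set(aln.row("a").residues) <= set("ACGT")

    def test_bad_length_rejected(self, wag):
        tree = sim.simulate_family_tree(seed=1)
        with pytest.raises(ValueError):
            sim.simulate_alignment(tree, wag, 0)


class TestProfilingDb:
    def test_composition_and_truth(self, family):
        aln, tree = family
        db, truth = sim.simulate_profiling_db(aln, tree, n_orthologs=20,
                                              n_contaminants=15, seed=10)
        assert len(db) == 35
        labels = list(truth.labels.values())
        assert labels.count(EUKARYOTE) == 20
        assert labels.count(PROKARYOTE) == 15
        euk_tips = {t for t in tree.tip_labels()
                    if tree.domain[t] == EUKARYOTE}
        for name, lab in truth.labels.items():
            src = truth.source_tip[name]
            assert (src in euk_tips) == (lab == EUKARYOTE)

    def test_fragment_length_floor(self, family):
        aln, tree = family
        db, _ = sim.simulate_profiling_db(aln, tree, n_orthologs=30,
                                          n_contaminants=0, seed=11)
        assert all(30 <= len(rec) <= 150 for rec in db)

    def test_unfragmented_full_length(self, family):
        aln, tree = family
        db, _ = sim.simulate_profiling_db(aln, tree, n_orthologs=5,
                                          n_contaminants=5, fragment=False,
                                          seed=12)
        assert all(len(rec) == 150 for rec in db)

    def test_score_method(self):
        truth = sim.ProfilingTruth(
            labels={"a": EUKARYOTE, "b": EUKARYOTE, "c": PROKARYOTE})
        recall, leakage = truth.score(["a", "c"])
        assert recall == 0.5 and leakage == 1.0

    def test_deterministic(self, family):
        aln, tree = family
        a, _ = sim.simulate_profiling_db(aln, tree, 5, 5, seed=13)
        b, _ = sim.simulate_profiling_db(aln, tree, 5, 5, seed=13)
        assert [(r.id, r.residues) for r in a] == [(r.id, r.residues) for r in b]


class TestRateTable:
    def test_structure(self):
        tab = sim.simulate_rate_table(n_specificities=12, seed=14)
        assert len(tab) == 24
        assert set(tab.columns) == {"specificity", "delta_mt", "X", "Y"}
        counts = tab.groupby("specificity")["delta_mt"].apply(
            lambda s: sorted(s.tolist()))
        assert all(v == [0, 1] for v in counts)
        shared_x = tab.groupby("specificity")["X"].nunique()
        assert (shared_x == 1).all()

    def test_noiseless_on_model_plane(self):
        betas = (0.1, 0.39, 0.38, 0.07)
        tab = sim.simulate_rate_table(betas, 10, sigma=0.0, seed=15)
        b0, b1, b2, b3 = betas
        pred = (b0 + b1 * tab.delta_mt + b2 * tab.X
                + b3 * tab.X * tab.delta_mt)
        assert np.abs(tab.Y - pred).max() < 1e-12

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            sim.simulate_rate_table(n_specificities=1)
        with pytest.raises(ValueError):
            sim.simulate_rate_table(sigma=-0.1)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=20)
    def test_x_in_range(self, seed):
        tab = sim.simulate_rate_table(n_specificities=5, seed=seed)
        assert tab.X.between(0.05, 0.8).all()


class TestReassignedGenome:
    def test_truth_bookkeeping(self):
        cds, alns, truth = sim.simulate_reassigned_genome(
            planted_fraction=0.8, seed=16)
        assert len(cds) == 6 and set(alns) == {r.id for r in cds}
        code = GeneticCode.from_ncbi(4)
        for rec in cds:
            codons = [rec.residues[i:i + 3] for i in range(0, len(rec), 3)]
            targets = [i for i, c in enumerate(codons) if c == "TGA"]
            assert targets == truth.per_gene_targets[rec.id]
            planted = set(truth.planted_columns[rec.id])
            assert planted <= set(targets)
            assert len(planted) == round(0.8 * len(targets))
            # non-target codons never use the target codon
            for i, c in enumerate(codons):
                if i not in targets:
                    assert c != "TGA"

    def test_planted_columns_have_planted_consensus(self):
        cds, alns, truth = sim.simulate_reassigned_genome(
            planted_fraction=1.0, planted_residue="S", conservation=1.0,
            gap_rate=0.0, seed=17)
        for rec in cds:
            aln = alns[rec.id]
            refs = aln.records[1:]
            for j in truth.planted_columns[rec.id]:
                col = [r.residues[j] for r in refs]
                assert set(col) == {"S"}

    def test_zero_fraction(self):
        cds, alns, truth = sim.simulate_reassigned_genome(
            planted_fraction=0.0, seed=18)
        assert all(not truth.planted_columns[r.id] for r in cds)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_reassigned_genome(planted_fraction=1.5)

    def test_deterministic(self):
        a, _, _ = sim.simulate_reassigned_genome(seed=19)
        b, _, _ = sim.simulate_reassigned_genome(seed=19)
        assert [(r.id, r.residues) for r in a] == [(r.id, r.residues) for r in b]
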