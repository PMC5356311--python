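import numpy as np
import pytest
from scipy import stats

from peroxevo.classify import classify_catalytic_profile
from peroxevo.models import build_model
from peroxevo.simulate import (SimulationError, SimulationSpec,
                               ancestor_recovery_experiment, evolve_sequences,
                               make_peroxidase_like_fixture, simulate_tree)
from peroxevo.reconstruct import ancestral_gap_mask


class TestSimulateTree:
    def test_two_leaves_is_a_cherry(self):
        tree = simulate_tree(2, 0.1, seed=1)
        assert len(tree.leaf_names()) == 2 and len(tree.internal_indices()) == 1

    def test_fixed_regime_sets_every_branch(self):
        tree = simulate_tree(9, 0.1, seed=2)
        assert np.allclose(tree.blen[tree.parent >= 0], 0.1)

    def test_range_regime_within_bounds(self):
        tree = simulate_tree(9, (0.05, 0.3), seed=3)
        bl = tree.blen[tree.parent >= 0]
        assert bl.min() >= 0.05 and bl.max() <= 0.3

    def test_seed_reproducibility(self):
        assert (simulate_tree(12, (0.01, 0.4), seed=5).to_newick()
                == simulate_tree(12, (0.01, 0.4), seed=5).to_newick())

    def test_too_few_leaves(self):
        with pytest.raises(SimulationError):
            simulate_tree(1, 0.1, seed=1)


class TestEvolveSequences:
    def test_zero_lengths_copy_root(self, wag):
        tree = simulate_tree(6, 0.0, seed=1)
        fam = evolve_sequences(SimulationSpec(tree, wag, 50, seed=2))
        root_seq = fam.sequences[tree.names[tree.root]]
        assert all(s == root_seq for s in fam.sequences.values())
        assert all(v == 0 for v in fam.visible_changes.values())

    def test_saturated_branch_reaches_equilibrium(self, wag):
        tree = simulate_tree(2, 1e4, seed=3)
        fam = evolve_sequences(SimulationSpec(tree, wag, 10000, seed=4))
        leaf = fam.sequences["L1"]
        counts = np.array([leaf.count(a) for a in "ACDEFGHIKLMNPQRSTVWY"])
        p = stats.chisquare(counts, wag.pi * len(leaf)).pvalue
        assert p > 0.001

    def test_identity_fraction_matches_analytic(self, wag):
        # fraction of sites unchanged across a branch of length t is
        # sum_i pi_i P_ii(t), binomial across sites
        t, L = 0.2, 5000
        tree = simulate_tree(2, t, seed=5)
        fam = evolve_sequences(SimulationSpec(tree, wag, L, seed=6))
        root = fam.sequences[tree.names[tree.root]]
        leaf = fam.sequences["L1"]
        obs = np.mean([a == b for a, b in zip(root, leaf)])
        P = wag.transition_matrix(t)
        expect = float(np.sum(wag.pi * np.diag(P)))
        sd = np.sqrt(expect * (1 - expect) / L)
        assert abs(obs - expect) <= 3 * sd

    def test_deterministic_given_seed(self, wag_gamma):
        tree = simulate_tree(5, 0.2, seed=7)
        a = evolve_sequences(SimulationSpec(tree, wag_gamma, 80, seed=8))
        b = evolve_sequences(SimulationSpec(tree, wag_gamma, 80, seed=8))
        assert a.sequences == b.sequences

    def test_overrides_applied_and_inherited(self, wag):
        tree = simulate_tree(6, 0.05, seed=9)
        root_name = tree.names[tree.root]
        fam = evolve_sequences(SimulationSpec(
            tree, wag, 30, seed=10, overrides=[(root_name, 0, "W")]))
        assert all(s[0] == "W" for s in fam.sequences.values())

    def test_override_reoverridden_downstream(self, wag):
        tree = simulate_tree(6, 0.05, seed=9)
        root_name = tree.names[tree.root]
        inner = tree.names[[i for i in tree.internal_indices()
                            if i != tree.root][0]]
        fam = evolve_sequences(SimulationSpec(
            tree, wag, 30, seed=10,
            overrides=[(root_name, 0, "W"), (inner, 0, "A")]))
        below = {tree.names[v] for v in tree.descendant_leaves(tree.index(inner))}
        for name in fam.tree.leaf_names():
            assert fam.sequences[name][0] == ("A" if name in below else "W")

    def test_override_unknown_node(self, wag):
        tree = simulate_tree(4, 0.1, seed=1)
        with pytest.raises(SimulationError, match="unknown node"):
            evolve_sequences(SimulationSpec(tree, wag, 10, seed=1,
                                            overrides=[("nope", 0, "W")]))

    def test_tail_truncation_drives_gap_mask(self, wag):
        tree = simulate_tree(8, 0.05, seed=12)
        # truncate the clade under the root's first internal child
        internals = [i for i in tree.internal_indices() if i != tree.root]
        node = tree.names[internals[0]]
        fam = evolve_sequences(SimulationSpec(tree, wag, 40, seed=13,
                                              truncate_tail=(node, 10)))
        aln = fam.leaf_alignment()
        mask = ancestral_gap_mask(tree, aln, node)
        assert mask[-10:].all() and not mask[:30].any()


class TestRecoveryExperiment:
    def test_zero_divergence_limit(self):
        df = ancestor_recovery_experiment([1e-6], replicates=2, seed=1,
                                          n_leaves=8, L=100)
        assert df["accuracy"].mean() >= 0.999

    def test_short_branches_more_accurate(self):
        df = ancestor_recovery_experiment([0.02, 0.5], replicates=3, seed=2,
                                          n_leaves=8, L=100)
        means = df.groupby("regime")["accuracy"].mean()
        assert means["0.02"] > means["0.5"]

    def test_deterministic(self):
        a = ancestor_recovery_experiment([0.1], replicates=2, seed=3,
                                         n_leaves=6, L=60)
        b = ancestor_recovery_experiment([0.1], replicates=2, seed=3,
                                         n_leaves=6, L=60)
        assert a.equals(b)


class TestPeroxidaseFixture:
    def test_designed_truth_types(self):
        fam, rules, sitemap, expected = make_peroxidase_like_fixture(seed=1)
        for node, want in expected.items():
            prof = classify_catalytic_profile(fam.sequences[node], sitemap, rules)
            assert prof.type_label == want, node

    def test_fixture_outputs(self, tmp_path):
        fam, *_ = make_peroxidase_like_fixture(seed=2)
        fam.write(tmp_path)
        assert (tmp_path / "leaves.fasta").exists()
        assert (tmp_path / "true_ancestors.fasta").exists()
        assert (tmp_path / "tree.nwk").exists()
        assert (tmp_path / "truth.json").exists()
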