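"""Tree model, newick I/O, mutation assignment and branch corrections."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonefate.readcounts import ReadCountMatrix
from clonefate.treecore import (
    NewickError,
    Node,
    Phylogeny,
    SensitivityProfile,
    assign_mutations_to_branches,
    bootstrap_branch_lengths,
    correct_branch_lengths,
    cut_tree_clones,
    make_ultrametric,
    prepare_time_tree,
    read_newick,
    somatic_sensitivity,
    write_newick,
)
from conftest import random_ultrametric_tree


class TestNewick:
    def test_parse_three_leaf_example(self):
        t = read_newick("((A:1,B:1):2,C:3);")
        depth = t.depths()
        assert depth[t.node("A")] == pytest.approx(3.0)
        assert len(t.leaves()) == 3

    def test_round_trip_preserves_cophenetic(self):
        rng = np.random.default_rng(0)
        t = random_ultrametric_tree(rng, 100)
        names1, d1 = t.cophenetic()
        t2 = read_newick(write_newick(t))
        names2, d2 = t2.cophenetic()
        order = [names2.index(n) for n in names1]
        np.testing.assert_allclose(d1, d2[np.ix_(order, order)], atol=1e-9)

    def test_auto_labels_deterministic_and_match_reference_parser(self):
        import dendropy

        s = "((A:1,B:2):0.5,(C:1,D:1):2);"
        t1, t2 = read_newick(s), read_newick(s)
        assert [n.name for n in t1.preorder()] == [n.name for n in t2.preorder()]
        ref = dendropy.Tree.get(data=s, schema="newick")
        ref_leaf_sets = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in ref.preorder_node_iter()
        }
        mine = {frozenset(l.name for l in t1.clade_leaves(n)) for n in t1.preorder()}
        assert mine == ref_leaf_sets

    def test_malformed_newick_names_offset(self):
        with pytest.raises(NewickError, match="offset"):
            read_newick("((A:1,B:1:2,C);")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(NewickError, match="duplicate"):
            read_newick("((A:1,A:1):2,C:3);")


def _counts(var: dict, dep: dict) -> ReadCountMatrix:
    v = pd.DataFrame(var).T
    d = pd.DataFrame(dep).T
    return ReadCountMatrix(v, d)


class TestAssignMutations:
    @pytest.fixture
    def tree(self, abc_tree):
        return abc_tree

    def test_perfect_signals(self, tree):
        counts = _counts(
            {"m_shared": {"A": 5, "B": 5, "C": 0}, "m_priv": {"A": 6, "B": 0, "C": 0}},
            {"m_shared": {"A": 10, "B": 10, "C": 10}, "m_priv": {"A": 12, "B": 10, "C": 10}},
        )
        out = assign_mutations_to_branches(tree, counts)
        assert "m_shared" in out["AB"]
        assert "m_priv" in out["A"]

    def test_noise_robust_and_matches_bruteforce(self, abc_tree):
        # one stray variant read in C must not move the assignment
        counts = _counts(
            {"m": {"A": 5, "B": 4, "C": 1}},
            {"m": {"A": 10, "B": 10, "C": 10}},
        )
        out = assign_mutations_to_branches(abc_tree, counts, epsilon=0.01)
        # brute-force oracle: enumerate branch likelihoods directly
        best, best_ll = None, -np.inf
        y = {"A": 5, "B": 4, "C": 1}
        n = {"A": 10, "B": 10, "C": 10}
        clades = {"A": {"A"}, "B": {"B"}, "C": {"C"}, "AB": {"A", "B"}}
        for branch, clade in clades.items():
            ll = 0.0
            for s in ("A", "B", "C"):
                p = 0.5 if s in clade else 0.01
                ll += stats.binom.logpmf(y[s], n[s], p)
            if ll > best_ll:
                best, best_ll = branch, ll
        assert out[best] == ["m"]
        assert best == "AB"

    def test_zero_depth_mutation_flagged(self, abc_tree):
        counts = _counts({"m": {"A": 0, "B": 0, "C": 0}},
                         {"m": {"A": 0, "B": 0, "C": 0}})
        with pytest.warns(UserWarning, match="unassignable"):
            out = assign_mutations_to_branches(abc_tree, counts)
        assert all("m" not in v for v in out.values())


class TestBranchCorrection:
    def test_printed_formulas(self, abc_tree):
        profile = SensitivityProfile({"A": 0.8, "B": 0.5, "C": 1.0})
        t = abc_tree.copy()
        t.node("A").length = 20.0
        t.node("AB").length = 10.0
        profile2 = SensitivityProfile({"A": 0.5, "B": 0.5, "C": 1.0})
        out = correct_branch_lengths(t, profile2)
        assert out.node("A").length == pytest.approx(20.0 / 0.5)
        assert out.node("AB").length == pytest.approx(10.0 / (1 - 0.25))
        out2 = correct_branch_lengths(t, profile)
        assert out2.node("A").length == pytest.approx(20.0 / 0.8)

    def test_identity_when_perfect(self, abc_tree):
        profile = SensitivityProfile({s: 1.0 for s in "ABC"})
        out = correct_branch_lengths(abc_tree, profile)
        for n1, n2 in zip(abc_tree.preorder(), out.preorder()):
            assert n1.length == pytest.approx(n2.length)

    def test_monotone_in_sensitivity(self, abc_tree):
        lo = correct_branch_lengths(abc_tree, SensitivityProfile({s: 0.6 for s in "ABC"}))
        hi = correct_branch_lengths(abc_tree, SensitivityProfile({s: 0.9 for s in "ABC"}))
        for a, b in zip(lo.preorder(), hi.preorder()):
            if a.parent is not None:
                assert a.length >= b.length - 1e-12

    def test_invalid_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            SensitivityProfile({"A": 0.0})


class TestSomaticSensitivity:
    def test_pure_colony_keeps_germline_sensitivity(self):
        p = somatic_sensitivity(0.9, 0.5, [10] * 100, np.ones((50, 50)), seed=0)
        assert p == pytest.approx(0.9)

    def test_perfect_matrix_gives_one(self):
        p = somatic_sensitivity(0.9, 0.3, [10] * 500, np.ones((60, 60)), seed=0)
        assert p == pytest.approx(1.0)

    def test_binomial_tail_oracle(self):
        # call iff n_v >= 3 at depth 10, peak VAF 0.4 -> P(Binom(10,0.4) >= 3)
        matrix = np.zeros((20, 20))
        matrix[3:, :] = 1.0
        p = somatic_sensitivity(0.95, 0.4, [10] * 200_000, matrix, seed=1)
        expected = 1 - stats.binom.cdf(2, 10, 0.4)
        assert expected == pytest.approx(0.8327, abs=1e-4)
        assert p == pytest.approx(expected, abs=0.005)

    def test_empty_depths_error(self):
        with pytest.raises(ValueError):
            somatic_sensitivity(0.9, 0.3, [], np.ones((5, 5)))


class TestTimeTree:
    def test_terminal_shortening_arithmetic(self):
        root = Node("root")
        ab = root.add_child(Node("AB", 40.0))
        ab.add_child(Node("A", 460.0))
        ab.add_child(Node("B", 480.0))
        t = Phylogeny(root)
        out = prepare_time_tree(t, rate_per_year=15.8, birth_burden=0.0,
                                terminal_shortening=60.0, sampling_age=30.0)
        depth = out.depths()
        # after shortening (400, 420) and ultrametric-isation, tips sit at 30y
        for leaf in out.leaves():
            assert depth[leaf] == pytest.approx(30.0, abs=1e-6)
        assert out.unit == "years"

    def test_ultrametric_idempotent_and_zero_variance(self):
        rng = np.random.default_rng(3)
        t = random_ultrametric_tree(rng, 30)
        for node in t.preorder():  # perturb
            if node.parent is not None:
                node.length = max(node.length + rng.normal(0, 2), 0.1)
        u1 = make_ultrametric(t)
        d = u1.depths()
        tips = np.array([d[l] for l in u1.leaves()])
        assert np.var(tips) == pytest.approx(0.0, abs=1e-12)
        u2 = make_ultrametric(u1)
        for a, b in zip(u1.preorder(), u2.preorder()):
            assert a.length == pytest.approx(b.length, abs=1e-9)


class TestBootstrap:
    def test_moments_and_poisson_limit(self):
        root = Node("root")
        root.add_child(Node("A", 100.0))
        root.add_child(Node("B", 100.0))
        t = Phylogeny(root)
        draws = np.array([
            b.node("A").length for b in bootstrap_branch_lengths(t, theta=10.0,
                                                                 n_boot=10_000, seed=0)
        ])
        # NegBinom(mu=100, theta=10): var = mu + mu^2/theta = 1100
        se = np.sqrt(1100 / 10_000)
        assert draws.mean() == pytest.approx(100.0, abs=3 * se)
        poisson = np.array([
            b.node("A").length for b in bootstrap_branch_lengths(t, theta=1e9,
                                                                 n_boot=10_000, seed=1)
        ])
        assert poisson.mean() == pytest.approx(100.0, abs=3 * np.sqrt(100 / 10_000) + 0.5)
        assert poisson.var() == pytest.approx(100.0, rel=0.1)

    def test_seed_determinism(self, abc_tree):
        a = bootstrap_branch_lengths(abc_tree, 5.0, 3, seed=7)
        b = bootstrap_branch_lengths(abc_tree, 5.0, 3, seed=7)
        for ta, tb in zip(a, b):
            assert write_newick(ta) == write_newick(tb)


class TestCloneCutting:
    def test_molecular_cut_from_root(self, clone_cut_tree):
        # ((A:90,B:90):60,C:150): at 50 mutations the cut crosses the shared
        # AB branch and C's terminal branch; at 100 it is past the AB split
        clones50 = cut_tree_clones(clone_cut_tree, 50.0)
        sets50 = {frozenset(l.name for l in c.leaves) for c in clones50}
        assert sets50 == {frozenset({"A", "B"}), frozenset({"C"})}
        clones100 = cut_tree_clones(clone_cut_tree, 100.0)
        sets100 = {frozenset(l.name for l in c.leaves) for c in clones100}
        assert sets100 == {frozenset({"A"}), frozenset({"B"}), frozenset({"C"})}

    def test_cut_zero_single_clone(self, clone_cut_tree):
        clones = cut_tree_clones(clone_cut_tree, 0.0)
        assert len(clones) == 1 and len(clones[0].leaves) == 3

    def test_cut_above_tips_warns_single_clone(self, clone_cut_tree):
        with pytest.warns(UserWarning, match="above all tips"):
            clones = cut_tree_clones(clone_cut_tree, 1e6)
        assert len(clones) == 1

    @pytest.mark.parametrize("cut", [1.0, 25.0, 60.0, 90.0, 149.0])
    def test_partition_property(self, cut):
        rng = np.random.default_rng(int(cut))
        t = random_ultrametric_tree(rng, 40, height=150.0)
        clones = cut_tree_clones(t, cut)
        all_leaves = [l.name for c in clones for l in c.leaves]
        assert sorted(all_leaves) == sorted(l.name for l in t.leaves())
        assert len(all_leaves) == len(set(all_leaves))
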