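"""Summary statistics: engraftment 13-vector, phylo-age 7-vector, diversity,
pruning/growth selection — checked against independent brute-force oracles."""

import dendropy
import numpy as np
import pytest

from clonefate.sumstats import (
    EpochDefinition,
    engraftment_stats13,
    expanded_clades,
    growth_stat,
    growth_statistic,
    mntd,
    mpd,
    phyloage_stats7,
    pruning_stat,
    pruning_statistic,
    selection_stat_ci,
)
from clonefate.treecore import Node, Phylogeny, write_newick
from conftest import random_ultrametric_tree


def _time_tree(newick_builder):
    t = newick_builder
    t.unit = "years"
    t.meta["ultrametric"] = True
    return t


def five_leaf_recipient():
    """Ultrametric 40-year tree with coalescences at 3, 24 and 26 years."""
    root = Node("root")
    a = root.add_child(Node("n3", 3.0))     # coalescence at 3y
    b = a.add_child(Node("n24", 21.0))      # coalescence at 24y
    b.add_child(Node("L1", 16.0))
    c = b.add_child(Node("n26", 2.0))       # coalescence at 26y
    c.add_child(Node("L2", 14.0))
    c.add_child(Node("L3", 14.0))
    a.add_child(Node("L4", 37.0))
    root.add_child(Node("L5", 40.0))
    t = Phylogeny(root, unit="years")
    t.meta["ultrametric"] = True
    return t


class TestEpochs:
    def test_presets_have_expected_windows(self):
        e = EpochDefinition.from_preset("original", 25.0)
        assert e.peri_intervals == [(20.0, 30.0)]
        assert e.pre_intervals == [(5.0, 20.0)]
        nar = EpochDefinition.from_preset("peri_interval_narrower", 25.0)
        assert nar.peri_intervals == [(22.5, 27.5)]
        div = EpochDefinition.from_preset("peri_interval_divided", 25.0)
        assert div.peri_intervals == [(20.0, 25.0), (25.0, 30.0)]

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            EpochDefinition.from_preset("bogus", 25.0)


class TestEngraftmentStats:
    def test_manual_epoch_counting(self):
        tree = five_leaf_recipient()
        epochs = EpochDefinition.from_preset("original", 25.0)
        s = engraftment_stats13(tree, tree, epochs)
        assert s["r_peri1"] == 2      # coalescences at 24 and 26
        assert s["r_pre1"] == 0       # the 3-year one is inside development
        assert len(s) == 13

    def test_identical_trees_are_symmetric(self):
        tree = five_leaf_recipient()
        epochs = EpochDefinition.from_preset("original", 25.0)
        s = engraftment_stats13(tree, tree, epochs)
        for i in (1, 2, 3):
            assert s[f"d_clade{i}"] == s[f"r_clade{i}"]
        assert s["d_singletons"] == s["r_singletons"]
        assert s["d_peri1"] == s["r_peri1"]
        assert s["d_pre1"] == s["r_pre1"]

    def test_swap_permutes_entries(self):
        rng = np.random.default_rng(7)
        t1, t2 = (random_ultrametric_tree(rng, 20, height=40.0) for _ in range(2))
        epochs = EpochDefinition.from_preset("original", 25.0)
        a = engraftment_stats13(t1, t2, epochs)
        b = engraftment_stats13(t2, t1, epochs)
        for i in (1, 2, 3):
            assert a[f"d_clade{i}"] == b[f"r_clade{i}"]
        assert a["d_singletons"] == b["r_singletons"]
        assert a["d_peri1"] == b["r_peri1"]
        assert a["d_pre1"] == b["r_pre1"]

    def test_star_tree(self):
        root = Node("root")
        for i in range(6):
            root.add_child(Node(f"L{i}", 40.0))
        t = Phylogeny(root, unit="years")
        t.meta["ultrametric"] = True
        epochs = EpochDefinition.from_preset("original", 25.0)
        s = engraftment_stats13(t, t, epochs)
        assert (s[["d_clade1", "d_clade2", "d_clade3"]] == 1).all()
        assert s["d_singletons"] == 6
        assert s["d_peri1"] == 0 and s["d_pre1"] == 0
        assert s["r_max_clade_peri"] == 0

    def test_non_time_tree_rejected(self):
        t = five_leaf_recipient()
        t.unit = "mutations"
        with pytest.raises(ValueError):
            engraftment_stats13(t, t, EpochDefinition.from_preset("original", 25.0))


class TestPhyloAgeStats:
    def test_all_coalescences_before_cutoff(self):
        # perfectly balanced tree with every split within the first 50 mutations
        root = Node("root")
        a = root.add_child(Node("a", 10.0))
        b = root.add_child(Node("b", 20.0))
        for i, p in enumerate((a, a, b, b)):
            p.add_child(Node(f"L{i}", 800.0))
        t = Phylogeny(root)
        s = phyloage_stats7(t)
        assert s["expanded_prop"] == 0.0
        assert s["singletons"] == 4

    def test_clade_sizes_enumeration(self):
        # ((a,b,c),(d,e),f) with post-cutoff ancestors -> sizes (3, 2, 1)
        root = Node("root")
        x = root.add_child(Node("x", 30.0))  # first split inside development
        abc = x.add_child(Node("abc", 40.0))
        for n in "abc":
            abc.add_child(Node(n, 700.0))
        de = x.add_child(Node("de", 100.0))
        for n in "de":
            de.add_child(Node(n, 640.0))
        x.add_child(Node("f", 740.0))
        t = Phylogeny(root)
        s = phyloage_stats7(t)
        assert (s["clade1"], s["clade2"], s["clade3"]) == (3.0, 2.0, 1.0)
        assert s["expanded_prop"] == pytest.approx(3 / 6)

    def test_centile_bin_counting(self):
        # height 800; one clade of 5 coalescing around 200 = 25th centile
        root = Node("root")
        top = root.add_child(Node("top", 190.0))
        prev = top
        for i in range(4):  # 4 further coalescences at 200..230
            nxt = prev.add_child(Node(f"n{i}", 10.0))
            prev.add_child(Node(f"L{i}", 800.0 - 190.0 - 10.0 * i))
            prev = nxt
        prev.add_child(Node("L4", 800.0 - 230.0))
        prev.add_child(Node("L5", 800.0 - 230.0))
        t = Phylogeny(root)
        s = phyloage_stats7(t)
        assert s["coal_20_40"] == 5.0  # splits at 200,210,220,230 and 230-node
        assert s["coal_40_60"] == 0.0


class TestDiversity:
    def test_two_leaves(self):
        root = Node("root")
        root.add_child(Node("A", 7.0))
        root.add_child(Node("B", 7.0))
        t = Phylogeny(root)
        assert mpd(t) == pytest.approx(14.0)
        assert mntd(t) == pytest.approx(14.0)

    def test_hand_cophenetic_example(self, abc_tree):
        assert mpd(abc_tree) == pytest.approx((2 + 6 + 6) / 3)
        assert mntd(abc_tree) == pytest.approx((2 + 2 + 6) / 3)

    def test_mpd_at_least_mntd(self):
        rng = np.random.default_rng(1)
        for k in range(5):
            t = random_ultrametric_tree(rng, 3 + 4 * k)
            assert mpd(t) >= mntd(t) - 1e-12

    def test_near_duplicate_leaf_lowers_mntd(self, abc_tree):
        before = mntd(abc_tree)
        a = abc_tree.node("A")
        a.add_child(Node("A1", 0.01))
        a.add_child(Node("A2", 0.01))
        after = mntd(abc_tree)
        assert after < before

    @pytest.mark.parametrize("n_leaves", [5, 9, 15])
    def test_matches_dendropy_oracle(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        t = random_ultrametric_tree(rng, n_leaves)
        dt = dendropy.Tree.get(data=write_newick(t), schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = list(dt.taxon_namespace)
        d = np.array([[pdm.patristic_distance(a, b) for b in taxa] for a in taxa])
        iu = np.triu_indices(n_leaves, k=1)
        assert mpd(t) == pytest.approx(d[iu].mean(), rel=1e-9)
        ref_mntd = np.mean([row[row > 0].min() for row in d])
        assert mntd(t) == pytest.approx(ref_mntd, rel=1e-9)


class TestExpandedClades:
    def test_threshold_rules(self):
        uniform = {f"c{i}": 1 / 200 for i in range(200)}
        assert expanded_clades(uniform).empty
        mixed = {"big": 10 / 200, "small": 1 / 200}
        out = expanded_clades(mixed)
        assert list(out["clone"]) == ["big"]
        assert expanded_clades(mixed, threshold=1.0).empty


class TestSelectionStatistics:
    def test_printed_formula(self):
        assert pruning_statistic(9, 9, 1, 4) == pytest.approx((10 / 10) / (2 / 5))
        assert pruning_statistic(0, 0, 0, 0) == pytest.approx(1.0)
        assert growth_statistic(9, 9, 1, 4) == pytest.approx(2.5)

    def test_identical_patterns_give_unity(self):
        t = five_leaf_recipient()
        epochs = EpochDefinition.from_preset("original", 25.0)
        clade = [l.name for l in t.leaves()][:4]
        assert pruning_stat(t, t, clade, clade, epochs) == pytest.approx(1.0)
        assert growth_stat(t, t, clade, clade, epochs) == pytest.approx(1.0)

    def test_absent_clade_guard(self):
        t = five_leaf_recipient()
        epochs = EpochDefinition.from_preset("original", 25.0)
        clade = ["L1", "L2", "L3"]
        val = pruning_stat(t, t, [], clade, epochs)
        assert np.isfinite(val) and val > 0

    def test_rescaling_invariance(self):
        t = five_leaf_recipient()
        epochs = EpochDefinition.from_preset("original", 25.0)
        clade = ["L1", "L2", "L3", "L4"]
        base = growth_stat(t, t, clade, clade, epochs)
        t2 = t.copy()
        for n in t2.preorder():
            n.length *= 3.0
        epochs2 = EpochDefinition(
            [(a * 3, b * 3) for a, b in epochs.pre_intervals],
            [(a * 3, b * 3) for a, b in epochs.peri_intervals],
        )
        t2.meta["ultrametric"] = True
        assert growth_stat(t2, t2, clade, clade, epochs2) == pytest.approx(base)

    def test_bruteforce_oracle_small_trees(self):
        # recompute clade-restricted window counts directly from node depths
        rng = np.random.default_rng(4)
        epochs = EpochDefinition.from_preset("original", 25.0)
        for rep in range(5):
            td = random_ultrametric_tree(rng, 12, height=40.0)
            tr = random_ultrametric_tree(rng, 12, height=40.0)
            clade_d = [l.name for l in td.leaves()][:6]
            clade_r = [l.name for l in tr.leaves()][:6]

            def brute(tree, clade):
                names = set(clade)
                depth = tree.depths()
                pre = tot = 0
                for node in tree.preorder():
                    if node.is_leaf or len(node.children) < 2:
                        continue
                    sides = sum(
                        1 for c in node.children
                        if any(l.name in names for l in tree.clade_leaves(c))
                    )
                    if sides >= 2:
                        tot += 1
                        if 5.0 <= depth[node] <= 20.0:
                            pre += 1
                return pre, tot

            pre_r, tot_r = brute(tr, clade_r)
            pre_d, tot_d = brute(td, clade_d)
            expected = pruning_statistic(pre_r, tot_r, pre_d, tot_d)
            assert pruning_stat(td, tr, clade_d, clade_r, epochs) == pytest.approx(expected)

    def test_bootstrap_ci(self):
        times_r = np.array([6.0, 8.0, 15.0, 22.0, 28.0])
        times_d = np.array([6.0, 30.0, 35.0])
        window = [(5.0, 20.0)]
        lo, hi = selection_stat_ci(times_r, times_d, window, n_boot=500, seed=0)
        assert lo <= hi
        lo2, hi2 = selection_stat_ci(times_r, times_d, window, n_boot=500, seed=0)
        assert (lo, hi) == (lo2, hi2)  # seeded determinism
        # degenerate single-node clades collapse to the point estimate
        lo3, hi3 = selection_stat_ci(np.array([10.0]), np.array([10.0]),
                                     window, n_boot=200, seed=1)
        assert lo3 == pytest.approx(hi3)
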