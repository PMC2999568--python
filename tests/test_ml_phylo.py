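"""Pruning likelihood, NJ, branch optimization, NNI, supports and tests."""

import itertools

import numpy as np
import pytest

from mat_alpha_trace.ml_phylo import (
    PruningEngine,
    distance_matrix,
    elw_edge_support,
    is_monophyletic,
    kh_sh_test,
    log_likelihood,
    neighbor_joining,
    nni_search,
    optimize_branch_lengths,
)
from mat_alpha_trace.models import lg_model
from mat_alpha_trace.profiles import Alignment
from mat_alpha_trace.simulate import (
    balanced_tree,
    evolve_on_tree,
    quartet_tree,
    sample_root,
)
from mat_alpha_trace.trees import PhyloTree


def brute_force_lnl(tree, alignment, model):
    """Likelihood by explicit summation over all internal-state
    assignments and rate components (independent of the pruning code)."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    root = nodes[-1]
    idx = {ch: i for i, ch in enumerate(model.alphabet)}
    rates = model.category_rates.tolist()
    weights = [(1.0 - (model.p_invariant or 0.0)) / len(rates)] * len(rates)
    if model.p_invariant:
        rates.append(0.0)
        weights.append(model.p_invariant)
    total = 0.0
    for site in range(alignment.n_columns):
        obs = {rid: alignment.row(rid)[site] for rid in alignment.ids}
        site_lik = 0.0
        for rate, w in zip(rates, weights):
            P = {
                id(n): model.transition_probabilities(n.length, rate)
                for n in nodes
                if n is not root
            }
            lik = 0.0
            for states in itertools.product(range(model.n_states), repeat=len(internals)):
                assign = dict(zip((id(n) for n in internals), states))
                p = model.frequencies[assign[id(root)]]
                for parent in tree.root.preorder():
                    if parent.is_leaf:
                        continue
                    for child in parent.children:
                        if child.is_leaf:
                            ch = obs[child.name]
                            if ch not in idx:
                                continue  # missing data: sums to 1
                            p *= P[id(child)][assign[id(parent)], idx[ch]]
                        else:
                            p *= P[id(child)][assign[id(parent)], assign[id(child)]]
                lik += p
            site_lik += w * lik
        total += np.log(site_lik)
    return total


def _random_toy_instance(rng, n_leaves, nsites, with_missing=False):
    names = [chr(65 + i) for i in range(n_leaves)]
    # random topology by sequential joining, random branch lengths
    from mat_alpha_trace.trees import TreeNode

    nodes = [TreeNode(name=nm, length=float(rng.uniform(0.05, 0.8))) for nm in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b], length=float(rng.uniform(0.05, 0.8))))
    tree = PhyloTree(TreeNode(children=nodes))
    alphabet = "ABC" + ("-" if with_missing else "")
    rows = ["".join(rng.choice(list(alphabet), size=nsites)) for _ in names]
    return tree, Alignment(names, rows)


class TestPruningOracle:
    @pytest.mark.parametrize("n_leaves", [3, 4, 5])
    def test_matches_bruteforce_enumeration(self, n_leaves, toy3_model):
        rng = np.random.default_rng(n_leaves)
        for rep in range(3):
            tree, aln = _random_toy_instance(rng, n_leaves, nsites=6)
            got = log_likelihood(tree, aln, toy3_model).total
            expected = brute_force_lnl(tree, aln, toy3_model)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_matches_bruteforce_with_missing_data(self, toy3_model_plain):
        rng = np.random.default_rng(99)
        tree, aln = _random_toy_instance(rng, 4, nsites=5, with_missing=True)
        got = log_likelihood(tree, aln, toy3_model_plain).total
        expected = brute_force_lnl(tree, aln, toy3_model_plain)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_two_leaf_closed_form_single_site(self, toy3_model_plain):
        """lnL of one site on a two-leaf tree: sum_i pi_i P_ia(t1) P_ib(t2),
        equal to pi_a P_ab(t1 + t2) by reversibility."""
        from mat_alpha_trace.trees import TreeNode

        m = toy3_model_plain
        t1, t2 = 0.3, 0.5
        tree = PhyloTree(
            TreeNode(children=[TreeNode(name="x", length=t1), TreeNode(name="y", length=t2)])
        )
        aln = Alignment(["x", "y"], ["A", "C"])
        got = log_likelihood(tree, aln, m).total
        P = m.transition_probabilities(t1 + t2)
        a, c = m.alphabet.index("A"), m.alphabet.index("C")
        assert got == pytest.approx(np.log(m.frequencies[a] * P[a, c]), rel=1e-12)

    def test_all_missing_column_contributes_zero(self, toy3_model):
        tree, _ = _random_toy_instance(np.random.default_rng(1), 4, 1)
        aln = Alignment(["A", "B", "C", "D"], ["-", "-", "-", "-"])
        assert log_likelihood(tree, aln, toy3_model).total == pytest.approx(0.0, abs=1e-12)

    def test_lnl_invariant_under_rerooting(self):
        rng = np.random.default_rng(11)
        model = lg_model(alpha=0.6)
        tree = balanced_tree(8, 0.6).unrooted_copy()
        root = sample_root(model.frequencies, 30, rng)
        leaves, _ = evolve_on_tree(tree.copy(), root, model, rng)
        aln = Alignment(sorted(leaves), [leaves[k] for k in sorted(leaves)])
        ref = log_likelihood(tree, aln, model).total
        internal_idx = [i for i, n in enumerate(tree.postorder()) if not n.is_leaf]
        for i in internal_idx[:4]:
            t2 = tree.copy()
            target = list(t2.postorder())[i]
            rerooted = t2.reroot_at_internal(target)
            assert log_likelihood(rerooted, aln, model).total == pytest.approx(ref, abs=1e-8)


class TestDistancesAndNJ:
    def test_identical_rows_have_zero_distance(self):
        aln = Alignment(["a", "b", "c"], ["ACDEFGHIKL"] * 2 + ["WWWWWWWWWW"])
        dmat, ids = distance_matrix(aln, lg_model())
        assert dmat[0, 1] < 1e-4
        assert np.allclose(dmat, dmat.T)
        assert np.allclose(np.diag(dmat), 0.0)

    def test_simulated_distance_recovered(self):
        model = lg_model()
        rng = np.random.default_rng(5)
        from mat_alpha_trace.trees import TreeNode

        tree = PhyloTree(
            TreeNode(
                children=[
                    TreeNode(name="x", length=0.15),
                    TreeNode(name="y", length=0.15),
                    TreeNode(name="z", length=5.0),
                ]
            )
        )
        root = sample_root(model.frequencies, 5000, rng)
        leaves, _ = evolve_on_tree(tree, root, model, rng)
        aln = Alignment(sorted(leaves), [leaves[k] for k in sorted(leaves)])
        dmat, ids = distance_matrix(aln, model)
        d = dmat[ids.index("x"), ids.index("y")]
        assert abs(d - 0.3) < 0.05

    def test_nj_recovers_additive_distances(self):
        # distances generated from ((A:0.1,B:0.2):0.05,C:0.3,D:0.4)
        true = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,C:0.3,D:0.4);")
        names = ["A", "B", "C", "D"]
        paths = {"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.4}
        dmat = np.zeros((4, 4))
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                if i == j:
                    continue
                extra = 0.05 if ({x, y} & {"A", "B"}) and ({x, y} & {"C", "D"}) else 0.0
                dmat[i, j] = paths[x] + paths[y] + extra
        tree = neighbor_joining(dmat, names)
        assert tree.is_monophyletic({"A", "B"})
        lengths = {n.name: n.length for n in tree.postorder() if n.is_leaf}
        for nm in names:
            assert lengths[nm] == pytest.approx(paths[nm], abs=1e-9)

    def test_three_taxa_closed_form(self):
        dmat = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = neighbor_joining(dmat, ["a", "b", "c"])
        lengths = {n.name: n.length for n in tree.postorder() if n.is_leaf}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(2)
        n = 6
        base = rng.uniform(0.2, 1.0, size=(n, n))
        dmat = (base + base.T) / 2.0
        np.fill_diagonal(dmat, 0.0)
        names = [f"t{i}" for i in range(n)]
        ref = {frozenset(b) for b in neighbor_joining(dmat, names).bipartitions()}
        perm = rng.permutation(n)
        got = {
            frozenset(b)
            for b in neighbor_joining(
                dmat[np.ix_(perm, perm)], [names[i] for i in perm]
            ).bipartitions()
        }
        assert ref == got

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(bad, ["a", "b", "c"])


class TestBranchOptimization:
    def _sim(self, seed, nsites=400):
        model = lg_model(alpha=0.8)
        rng = np.random.default_rng(seed)
        tree = balanced_tree(8, 0.6).unrooted_copy()
        root = sample_root(model.frequencies, nsites, rng)
        leaves, _ = evolve_on_tree(tree.copy(), root, model, rng)
        aln = Alignment(sorted(leaves), [leaves[k] for k in sorted(leaves)])
        return tree, aln, model

    def test_lnl_non_decreasing_and_improving(self):
        tree, aln, model = self._sim(0)
        start = log_likelihood(tree, aln, model).total
        opt, lnl = optimize_branch_lengths(tree, aln, model)
        assert lnl >= start

    def test_idempotent_at_optimum(self):
        tree, aln, model = self._sim(1)
        opt, lnl1 = optimize_branch_lengths(tree, aln, model)
        _, lnl2 = optimize_branch_lengths(opt, aln, model)
        assert abs(lnl2 - lnl1) < 1e-2

    def test_branch_length_recovery(self):
        """Simulated branch lengths recovered within 20% on most branches."""
        model = lg_model(alpha=0.8)
        rng = np.random.default_rng(3)
        from mat_alpha_trace.trees import TreeNode

        # fixed 6-leaf unrooted tree with assorted lengths
        newick = "((A:0.2,B:0.35):0.15,(C:0.25,D:0.4):0.2,(E:0.3,F:0.2):0.1);"
        tree = PhyloTree.from_newick(newick)
        root = sample_root(model.frequencies, 2000, rng)
        leaves, _ = evolve_on_tree(tree.copy(), root, model, rng)
        aln = Alignment(sorted(leaves), [leaves[k] for k in sorted(leaves)])
        start = PhyloTree.from_newick(newick)
        for _, child in start.edges():
            child.length = 0.3  # forget the truth
        opt, _ = optimize_branch_lengths(start, aln, model)
        true_lengths = {
            frozenset(c.leaf_names()): c.length for _, c in PhyloTree.from_newick(newick).edges()
        }
        est_lengths = {frozenset(c.leaf_names()): c.length for _, c in opt.edges()}
        ok = 0
        for bip, t in true_lengths.items():
            e = est_lengths[bip]
            ok += abs(e - t) / t <= 0.2
        assert ok >= 0.8 * len(true_lengths)


class TestNNI:
    def test_true_topology_is_local_optimum_on_strong_data(self):
        model = lg_model(alpha=0.8)
        rng = np.random.default_rng(8)
        tree = quartet_tree(1.0, 0.1)
        root = sample_root(model.frequencies, 500, rng)
        leaves, _ = evolve_on_tree(tree.copy(), root, model, rng)
        aln = Alignment(sorted(leaves), [leaves[k] for k in sorted(leaves)])
        best, lnl = nni_search(tree, aln, model)
        assert best.is_monophyletic({"A", "B"})
        assert lnl >= log_likelihood(tree, aln, model).total

    def test_returned_lnl_not_below_start(self):
        model = lg_model(alpha=0.8)
        rng = np.random.default_rng(9)
        tree = balanced_tree(8, 0.5).unrooted_copy()
        root = sample_root(model.frequencies, 60, rng)
        leaves, _ = evolve_on_tree(tree.copy(), root, model, rng)
        aln = Alignment(sorted(leaves), [leaves[k] for k in sorted(leaves)])
        start_lnl = log_likelihood(tree, aln, model).total
        _, lnl = nni_search(tree, aln, model)
        assert lnl >= start_lnl - 1e-9


class TestMonophyly:
    def test_four_leaf_bipartitions(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(tree, ["A", "B"])
        assert not is_monophyletic(tree, ["A", "C"])

    def test_trivial_groups(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(tree, ["A"])
        assert is_monophyletic(tree, ["A", "B", "C", "D"])

    def test_foreign_taxa_rejected(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            is_monophyletic(tree, ["A", "Z"])


class TestSupportsAndTests:
    def _quartet_data(self, internal, seed, nsites=300):
        model = lg_model(alpha=0.8)
        rng = np.random.default_rng(seed)
        tree = quartet_tree(internal, 0.1)
        root = sample_root(model.frequencies, nsites, rng)
        leaves, _ = evolve_on_tree(tree.copy(), root, model, rng)
        aln = Alignment(sorted(leaves), [leaves[k] for k in sorted(leaves)])
        return tree, aln, model

    def test_weights_sum_to_100(self):
        tree, aln, model = self._quartet_data(0.3, 0)
        opt, _ = optimize_branch_lengths(tree, aln, model)
        report = elw_edge_support(opt, aln, model, n_replicates=500, seed=3)
        for s in report.supports:
            assert s.weights_pct.sum() == pytest.approx(100.0, abs=0.1)

    def test_bit_reproducible_for_fixed_seed(self):
        tree, aln, model = self._quartet_data(0.5, 1)
        opt, _ = optimize_branch_lengths(tree, aln, model)
        r1 = elw_edge_support(opt, aln, model, n_replicates=400, seed=7)
        r2 = elw_edge_support(opt, aln, model, n_replicates=400, seed=7)
        assert [s.support for s in r1.supports] == [s.support for s in r2.supports]
        k1 = kh_sh_test([tree, opt], aln, model, n_replicates=400, seed=7)
        k2 = kh_sh_test([tree, opt], aln, model, n_replicates=400, seed=7)
        assert [(r.kh_p, r.sh_p) for r in k1] == [(r.kh_p, r.sh_p) for r in k2]

    def test_low_replicate_count_warns(self):
        tree, aln, model = self._quartet_data(0.5, 2)
        opt, _ = optimize_branch_lengths(tree, aln, model)
        with pytest.warns(UserWarning):
            elw_edge_support(opt, aln, model, n_replicates=50, seed=1)

    def test_self_comparison_kh_p_is_one(self):
        tree, aln, model = self._quartet_data(0.5, 3)
        res = kh_sh_test([tree, tree.copy()], aln, model, n_replicates=500, seed=5)
        assert all(r.kh_p == pytest.approx(1.0) for r in res)

    def test_best_topology_gets_p_one(self):
        tree, aln, model = self._quartet_data(0.8, 4)
        wrong = PhyloTree.from_newick("((A:0.1,C:0.1):0.4,(B:0.1,D:0.1):0.4);")
        res = kh_sh_test([tree, wrong], aln, model, n_replicates=500, seed=5)
        best = [r for r in res if r.is_best][0]
        assert best.kh_p == pytest.approx(1.0)
        assert best.sh_p == pytest.approx(1.0)

    def test_wrong_grouping_rejected_on_strong_data(self):
        """A topology with a huge lnL deficit gets a small KH p-value."""
        rejections = 0
        for seed in range(10):
            tree, aln, model = self._quartet_data(1.0, 50 + seed, nsites=300)
            wrong = PhyloTree.from_newick("((A:0.1,C:0.1):0.5,(B:0.1,D:0.1):0.5);")
            res = kh_sh_test([tree, wrong], aln, model, n_replicates=1000, seed=seed)
            worst = [r for r in res if not r.is_best]
            if worst and worst[0].kh_p < 0.05:
                rejections += 1
        assert rejections >= 8
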