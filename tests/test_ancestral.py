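"""Marginal ancestral reconstruction against brute-force posteriors."""

import itertools

import numpy as np
import pytest

from mat_alpha_trace.ancestral import (
    marginal_posteriors,
    reconstruct_class_ancestor,
    reconstruct_family_ancestors,
)
from mat_alpha_trace.models import lg_model
from mat_alpha_trace.profiles import Alignment
from mat_alpha_trace.simulate import balanced_tree, evolve_on_tree, sample_root
from mat_alpha_trace.trees import PhyloTree, TreeNode


def brute_force_root_posterior(tree, alignment, model, site):
    """Posterior over root states by explicit enumeration (Bayes rule over
    all internal-state assignments and rate components)."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    root = nodes[-1]
    idx = {ch: i for i, ch in enumerate(model.alphabet)}
    rates = model.category_rates.tolist()
    weights = [(1.0 - (model.p_invariant or 0.0)) / len(rates)] * len(rates)
    if model.p_invariant:
        rates.append(0.0)
        weights.append(model.p_invariant)
    obs = {rid: alignment.row(rid)[site] for rid in alignment.ids}
    mass = np.zeros(model.n_states)
    for rate, w in zip(rates, weights):
        P = {
            id(n): model.transition_probabilities(n.length, rate)
            for n in nodes
            if n is not root
        }
        for states in itertools.product(range(model.n_states), repeat=len(internals)):
            assign = dict(zip((id(n) for n in internals), states))
            p = w * model.frequencies[assign[id(root)]]
            for parent in tree.root.preorder():
                if parent.is_leaf:
                    continue
                for child in parent.children:
                    if child.is_leaf:
                        ch = obs[child.name]
                        if ch in idx:
                            p *= P[id(child)][assign[id(parent)], idx[ch]]
                    else:
                        p *= P[id(child)][assign[id(parent)], assign[id(child)]]
            mass[assign[id(root)]] += p
    return mass / mass.sum()


class TestMarginalPosteriors:
    def test_zero_branches_identical_leaves_give_certainty(self):
        tree = PhyloTree(
            TreeNode(
                children=[
                    TreeNode(name="a", length=0.0),
                    TreeNode(name="b", length=0.0),
                    TreeNode(name="c", length=0.0),
                ]
            )
        )
        aln = Alignment(["a", "b", "c"], ["WKV", "WKV", "WKV"])
        rec = marginal_posteriors(tree, aln, lg_model(alpha=0.7))
        assert rec.map_residues == "WKV"
        assert np.all(rec.map_probability > 1.0 - 1e-9)

    def test_matches_bruteforce_enumeration(self, toy3_model):
        rng = np.random.default_rng(0)
        tree = PhyloTree(
            TreeNode(
                children=[
                    TreeNode(name="a", length=0.4),
                    TreeNode(name="b", length=0.2),
                    TreeNode(
                        children=[
                            TreeNode(name="c", length=0.7),
                            TreeNode(name="d", length=0.1),
                        ],
                        length=0.3,
                    ),
                ]
            )
        )
        rows = ["AB", "BB", "CA", "A-"]
        aln = Alignment(["a", "b", "c", "d"], rows)
        rec = marginal_posteriors(tree, aln, toy3_model)
        for site in range(2):
            expected = brute_force_root_posterior(tree, aln, toy3_model, site)
            assert np.abs(rec.posteriors[site] - expected).max() < 1e-10

    def test_matches_bruteforce_with_invariant_sites(self, toy3_model):
        """The invariant-site spike participates correctly in the
        posterior, and MAP residues use the model's own alphabet."""
        model = toy3_model.with_params(p_invariant=0.2)
        tree = PhyloTree.from_newick("((a:0.2,b:0.3):0.15,(c:0.25,d:0.1):0.2);")
        aln = Alignment(["a", "b", "c", "d"], ["AB", "AB", "AC", "AB"])
        rec = marginal_posteriors(tree, aln, model)
        for site in range(2):
            expected = brute_force_root_posterior(tree, aln, model, site)
            assert np.abs(rec.posteriors[site] - expected).max() < 1e-10
        assert set(rec.map_residues) <= set("ABC")

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        model = lg_model(alpha=0.8)
        tree = balanced_tree(8, 0.5)
        root = sample_root(model.frequencies, 25, rng)
        leaves, _ = evolve_on_tree(tree.copy(), root, model, rng)
        aln = Alignment(sorted(leaves), [leaves[k] for k in sorted(leaves)])
        rec = marginal_posteriors(tree, aln, model)
        assert np.allclose(rec.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_internal_non_root_node_reconstruction(self, toy3_model_plain):
        tree = PhyloTree.from_newick("((a:0.2,b:0.3):0.15,(c:0.25,d:0.1):0.2);")
        aln = Alignment(["a", "b", "c", "d"], ["A", "A", "C", "C"])
        node = next(
            n for n in tree.postorder()
            if not n.is_leaf and set(n.leaf_names()) == {"a", "b"}
        )
        rec = marginal_posteriors(tree, aln, toy3_model_plain, node=node)
        assert rec.map_residues == "A"

    def test_leaf_node_rejected(self, toy3_model_plain):
        tree = PhyloTree.from_newick("((a:0.2,b:0.3):0.15,(c:0.25,d:0.1):0.2);")
        aln = Alignment(["a", "b", "c", "d"], ["A", "A", "C", "C"])
        leaf = next(n for n in tree.postorder() if n.is_leaf)
        with pytest.raises(ValueError):
            marginal_posteriors(tree, aln, toy3_model_plain, node=leaf)


class TestFamilyAncestors:
    def _family(self, seed, height=0.5, n=8, nsites=40, root=None):
        model = lg_model(alpha=0.8)
        rng = np.random.default_rng(seed)
        if root is None:
            root = sample_root(model.frequencies, nsites, rng)
        tree = balanced_tree(n, height, prefix=f"f{seed}_")
        leaves, _ = evolve_on_tree(tree, root, model, rng)
        return root, Alignment(sorted(leaves), [leaves[k] for k in sorted(leaves)])

    def test_identical_families_give_identical_ancestors(self):
        _, aln = self._family(0)
        a, b, res = reconstruct_family_ancestors(aln, aln)
        assert a.map_residues == b.map_residues
        assert res.identity_pct == pytest.approx(100.0)

    def test_map_ancestor_recovers_simulated_root(self):
        root, aln = self._family(1, height=0.5, n=16)
        rec = reconstruct_class_ancestor(aln)
        ident = sum(x == y for x, y in zip(rec.map_residues, root)) / len(root)
        assert ident >= 0.8

    def test_order_invariance(self):
        _, aln = self._family(2)
        perm = list(reversed(range(aln.n_rows)))
        shuffled = Alignment([aln.ids[i] for i in perm], [aln.rows[i] for i in perm])
        r1 = reconstruct_class_ancestor(aln)
        r2 = reconstruct_class_ancestor(shuffled)
        assert r1.map_residues == r2.map_residues

    def test_ancestors_denoise_relative_to_leaves(self):
        """Two families from one root: ancestor-vs-ancestor identity beats
        the mean leaf-vs-leaf cross-family identity."""
        model = lg_model(alpha=0.8)
        rng = np.random.default_rng(7)
        shared_root = sample_root(model.frequencies, 40, rng)
        _, aln_a = self._family(10, height=0.6, root=shared_root)
        _, aln_b = self._family(11, height=0.6, root=shared_root)
        anc_a, anc_b, res = reconstruct_family_ancestors(aln_a, aln_b)
        anc_ident = sum(
            x == y for x, y in zip(anc_a.map_residues, anc_b.map_residues)
        ) / 40.0
        cross = []
        for ra in aln_a.rows:
            for rb in aln_b.rows:
                cross.append(sum(x == y for x, y in zip(ra, rb)) / 40.0)
        assert anc_ident > np.mean(cross)

    def test_small_family_rejected(self):
        aln = Alignment(["a", "b"], ["ACDEF", "ACDEW"])
        with pytest.raises(ValueError):
            reconstruct_class_ancestor(aln)
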