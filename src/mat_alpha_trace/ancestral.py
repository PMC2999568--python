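"""Marginal maximum-likelihood ancestral sequence reconstruction.

The marginal posterior of the residue at an internal node is
proportional to pi_s times the product of the partial likelihoods of the
subtrees hanging off that node, summed over rate components weighted by
their per-site posterior weights. The MAP residue string is read off the
per-site posteriors (ties broken alphabetically).

Ancestors are reconstructed on core alignment columns only; indels are
not reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .compare import ComparisonResult, compare_consensus
from .ml_phylo import PruningEngine, distance_matrix, neighbor_joining, optimize_branch_lengths
from .models import RateModel, lg_model
from .profiles import Alignment
from .sequences import AMINO_ACIDS
from .trees import PhyloTree, TreeNode


@dataclass
class AncestralReconstruction:
    """Per-site residue posteriors at one internal node."""

    node_label: str
    posteriors: np.ndarray  # (nsites, 20) over ACDEFGHIKLMNPQRSTVWY
    map_residues: str
    map_probability: np.ndarray  # (nsites,)

    def __post_init__(self) -> None:
        assert np.allclose(self.posteriors.sum(axis=1), 1.0, atol=1e-9)


def marginal_posteriors(
    tree: PhyloTree,
    alignment: Alignment,
    model: RateModel,
    node: TreeNode | None = None,
    node_label: str = "root",
) -> AncestralReconstruction:
    """Marginal residue posteriors at an internal node.

    ``node`` defaults to the tree's root; otherwise it must be an internal
    node of ``tree`` (the tree is re-rooted there, which leaves the
    likelihood unchanged under a reversible model).
    """
    if node is not None and node is not tree.root:
        if node.is_leaf:
            raise ValueError("ancestral states are reconstructed at internal nodes")
        if not any(n is node for n in tree.postorder()):
            raise ValueError("node not found in tree")
        tree = tree.reroot_at_internal(node)
    engine = PruningEngine(tree, alignment, model)
    engine.compute_down()
    root = engine.down[engine.root_idx]  # (ncat, nsites, 20)
    logsc = engine.down_logsc[engine.root_idx]  # (ncat, nsites)
    pi = model.frequencies
    ncat = engine.ncat
    pinv = engine.pinv
    with np.errstate(divide="ignore"):
        # joint log-mass over (component, state): gamma categories ...
        log_joint = (
            np.log(root * pi[None, None, :])
            + logsc[:, :, None]
            + np.log((1.0 - pinv) / ncat)
        )
        if pinv > 0.0:
            # ... plus the invariant spike (only states consistent with
            # every observed leaf residue carry mass)
            compat = np.ones((engine.nsites, engine.nstates))
            for i in np.where(engine.is_leaf)[0]:
                compat *= engine.down[int(i), 0]
            inv = np.log(pinv * pi[None, :] * compat)
            log_joint = np.concatenate([log_joint, inv[None, :, :]], axis=0)
    log_state = logsumexp(log_joint, axis=0)  # (nsites, nstates)
    log_state -= logsumexp(log_state, axis=1, keepdims=True)
    post = np.exp(log_state)
    post /= post.sum(axis=1, keepdims=True)
    best = post.argmax(axis=1)  # first index on ties -> alphabetical
    residues = "".join(model.alphabet[i] for i in best)
    return AncestralReconstruction(
        node_label=node_label,
        posteriors=post,
        map_residues=residues,
        map_probability=post[np.arange(post.shape[0]), best],
    )


def reconstruct_class_ancestor(
    alignment: Alignment,
    model: RateModel | None = None,
    label: str = "ancestor",
) -> AncestralReconstruction:
    """Ancestor at the midpoint root of a single class's core alignment.

    Infers an NJ tree from ML pairwise distances, optimizes branch
    lengths, midpoint-roots the class subtree (no outgroup exists within
    a class) and reconstructs the root's marginal posteriors.
    """
    if alignment.n_rows < 3:
        raise ValueError("need at least 3 sequences per class")
    model = model or lg_model(alpha=1.0)
    dmat, ids = distance_matrix(alignment, model)
    tree = neighbor_joining(dmat, ids)
    tree, _ = optimize_branch_lengths(tree, alignment, model)
    rooted = tree.midpoint_root()
    return marginal_posteriors(rooted, alignment, model, node_label=label)


def reconstruct_family_ancestors(
    alignment_a: Alignment,
    alignment_b: Alignment,
    model: RateModel | None = None,
    label_a: str = "class_a",
    label_b: str = "class_b",
) -> tuple[AncestralReconstruction, AncestralReconstruction, ComparisonResult]:
    """Per-class root ancestors for two domain classes plus their comparison."""
    anc_a = reconstruct_class_ancestor(alignment_a, model, label_a)
    anc_b = reconstruct_class_ancestor(alignment_b, model, label_b)
    result = compare_consensus(
        anc_a.map_residues, anc_b.map_residues, query_id=label_a, subject_id=label_b
    )
    return anc_a, anc_b, result


def write_ancestor_outputs(anc: AncestralReconstruction, fasta_path, tsv_path) -> None:
    """MAP ancestor FASTA plus per-site posterior TSV."""
    import pandas as pd

    with open(fasta_path, "w") as fh:
        fh.write(f">{anc.node_label}\n{anc.map_residues}\n")
    df = pd.DataFrame(anc.posteriors, columns=list(AMINO_ACIDS))
    df.insert(0, "site", np.arange(1, anc.posteriors.shape[0] + 1))
    df["map"] = list(anc.map_residues)
    df["map_prob"] = anc.map_probability
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
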