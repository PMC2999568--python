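"""Synthetic domain-family datasets with full ground truth.

Generates four-class datasets with the statistical structure the
analysis assumes: the classes descend from a common ancestor under an
empirical amino-acid model with gamma rate heterogeneity; the alpha1
clade is nested *inside* the MATA_HMG group (making MATA_HMG
paraphyletic), with SOX and HMGB successively more distant; the alpha1
subclasses carry terminal core truncations (-2 for the Pleosporales-like
alpha1-a, -4 for alpha1-b); and full-length proteins optionally carry a
planted PROSITE motif instance a short distance downstream of the domain
in the alpha1 classes only. Every latent quantity (true tree, true
ancestral sequences, motif positions) is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .models import RateModel, lg_model
from .motif_scan import ALPHA1_DOWNSTREAM_CORE, parse_pattern, sample_pattern_instance
from .profiles import Alignment
from .sequences import AMINO_ACIDS, GAP, DomainClass, DomainSequence
from .trees import PhyloTree, TreeNode

_AA = np.array(list(AMINO_ACIDS))


@dataclass
class SimulationConfig:
    """Study conditions for the planted-history synthetic dataset.

    Defaults are desk-scale: 48 taxa (6 alpha1-a, 6 alpha1-b, 12
    MATA_HMG, 12 SOX, 12 HMGB) over a 40-column core evolved under LG+G
    with shape 0.8.
    """

    seed: int
    n_per_class: Mapping[DomainClass, int] = field(
        default_factory=lambda: {
            DomainClass.ALPHA1_A: 6,
            DomainClass.ALPHA1_B: 6,
            DomainClass.MATA_HMG: 12,
            DomainClass.SOX: 12,
            DomainClass.HMGB: 12,
        }
    )
    core_length: int = 40
    alpha: float = 0.8
    n_categories: int = 4
    #: expected substitutions/site on within-class edges
    intra_branch_length: float = 0.05
    #: stem length subtending each class clade (set so that the recovered
    #: class edges carry LR-ELW supports in the 80-100 range, the regime
    #: the real domain classes show)
    class_stem_length: float = 0.5
    #: backbone edges connecting the class stems (set so the deep
    #: between-class edges carry supports in the 70-100 range)
    backbone_length: float = 0.45
    truncation: Mapping[DomainClass, int] = field(
        default_factory=lambda: {DomainClass.ALPHA1_A: 2, DomainClass.ALPHA1_B: 4}
    )
    motif_pattern: str = ALPHA1_DOWNSTREAM_CORE
    motif_classes: tuple[DomainClass, ...] = (DomainClass.ALPHA1_A, DomainClass.ALPHA1_B)
    #: planted-motif offset after the domain end, sampled in [0, max]
    motif_max_offset: int = 53
    n_flank_length: int = 30
    downstream_length: int = 80
    hmgb_insert_length: int = 6
    hmgb_insert_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.core_length <= 0:
            raise ValueError("core_length must be positive")
        for cls, k in self.truncation.items():
            if k >= self.core_length:
                raise ValueError(f"truncation {k} for {cls} >= core length")


@dataclass
class GroundTruth:
    tree: PhyloTree
    newick: str
    ancestors: dict[str, str]
    motif_positions: dict[str, tuple[int, str]]  # id -> (1-based start, instance)
    class_of: dict[str, DomainClass]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    cores: list[DomainSequence]
    true_alignment: Alignment
    proteins: list[DomainSequence]
    domain_end: dict[str, int]  # 1-based end of the core in each protein
    truth: GroundTruth

    def cores_by_class(self, cls: DomainClass) -> list[DomainSequence]:
        return [s for s in self.cores if s.domain_class is cls]


# -- elementary generators -------------------------------------------------


def sample_root(freqs: Sequence[float], length: int, rng: np.random.Generator) -> str:
    """i.i.d. residue string from a frequency vector (or profile rows)."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim == 1:
        if abs(freqs.sum() - 1.0) > 1e-6:
            raise ValueError("frequencies must sum to 1")
        idx = rng.choice(20, size=length, p=freqs)
    else:
        if freqs.shape != (length, 20):
            raise ValueError("profile shape must be (length, 20)")
        idx = np.array([rng.choice(20, p=row / row.sum()) for row in freqs])
    return "".join(_AA[idx]) if length else ""


def draw_site_rates(model: RateModel, length: int, rng: np.random.Generator) -> np.ndarray:
    """Per-site relative rates: one gamma category per site (plus the
    invariant spike when the model has one), fixed across branches."""
    rates = model.category_rates
    out = rates[rng.integers(0, len(rates), size=length)]
    if model.p_invariant:
        out = np.where(rng.random(length) < model.p_invariant, 0.0, out)
    return out


def _evolve_codes(
    parent: np.ndarray, t: float, rates: np.ndarray, model: RateModel, rng: np.random.Generator
) -> np.ndarray:
    child = parent.copy()
    for rate in np.unique(rates):
        if rate == 0.0:
            continue
        sites = np.where(rates == rate)[0]
        P = model.transition_probabilities(t, float(rate))
        probs = P[parent[sites]]
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(len(sites))
        child[sites] = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
    return child


def evolve_on_tree(
    tree: PhyloTree,
    root_seq: str,
    model: RateModel,
    rng: np.random.Generator,
    site_rates: np.ndarray | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Simulate residues down a rooted tree with branch lengths.

    Per-site gamma rates are drawn once at the root and shared by all
    branches (matching the inference model). Returns (leaf sequences,
    internal-node sequences); unnamed internal nodes are labelled
    ``anc<i>`` in preorder, the root being ``anc0``.
    """
    codes = np.array([AMINO_ACIDS.index(ch) for ch in root_seq])
    if site_rates is None:
        site_rates = draw_site_rates(model, len(root_seq), rng)
    leaves: dict[str, str] = {}
    internals: dict[str, str] = {}
    counter = 0
    for node in tree.root.preorder():
        if not node.is_leaf and not node.name:
            node.name = f"anc{counter}"
        counter += not node.is_leaf

    def walk(node: TreeNode, state: np.ndarray) -> None:
        seq = "".join(_AA[state])
        if node.is_leaf:
            leaves[node.name] = seq
        else:
            internals[node.name] = seq
        for child in node.children:
            walk(child, _evolve_codes(state, child.length, site_rates, model, rng))

    walk(tree.root, codes)
    return leaves, internals


def apply_class_truncation(
    seqs: Sequence[DomainSequence],
    spec: Mapping[DomainClass, int],
    end: str = "C",
) -> list[DomainSequence]:
    """Remove a fixed number of terminal residues from designated classes."""
    out = []
    for s in seqs:
        k = spec.get(s.domain_class, 0)
        if k == 0:
            out.append(s)
            continue
        if k >= len(s):
            raise ValueError(f"truncation {k} >= sequence length for {s.id}")
        residues = s.residues[:-k] if end == "C" else s.residues[k:]
        out.append(DomainSequence(s.id, residues, taxon=s.taxon, domain_class=s.domain_class))
    return out


def build_full_proteins(
    cores: Sequence[DomainSequence],
    config: SimulationConfig,
    model: RateModel,
    rng: np.random.Generator,
) -> tuple[list[DomainSequence], dict[str, int], dict[str, tuple[int, str]]]:
    """Embed cores in random flanks, planting a motif instance downstream
    of the domain in the designated classes.

    Returns (proteins, 1-based domain end per id, motif positions per id).
    """
    pattern = parse_pattern(config.motif_pattern)
    if config.downstream_length < pattern.min_length:
        raise ValueError("downstream flank shorter than the motif")
    pi = model.frequencies
    proteins: list[DomainSequence] = []
    domain_end: dict[str, int] = {}
    motif_positions: dict[str, tuple[int, str]] = {}
    for core in cores:
        n_flank = sample_root(pi, config.n_flank_length, rng)
        down = list(sample_root(pi, config.downstream_length, rng))
        if core.domain_class in config.motif_classes:
            instance = sample_pattern_instance(pattern, rng)
            max_off = min(config.motif_max_offset, config.downstream_length - len(instance))
            offset = int(rng.integers(0, max_off + 1))
            down[offset : offset + len(instance)] = list(instance)
            start = len(n_flank) + len(core.residues) + offset + 1
            motif_positions[core.id] = (start, instance)
        residues = n_flank + core.residues + "".join(down)
        proteins.append(
            DomainSequence(core.id, residues, taxon=core.taxon, domain_class=core.domain_class)
        )
        domain_end[core.id] = len(n_flank) + len(core.residues)
    return proteins, domain_end, motif_positions


# -- the planted-history dataset ----------------------------------------------


def _random_clade(
    prefix: str, n: int, blen: float, rng: np.random.Generator
) -> tuple[TreeNode, list[str]]:
    """Random bifurcating subtree over n leaves, all edges ~ blen."""
    names = [f"{prefix}{i + 1:03d}" for i in range(n)]
    nodes = [TreeNode(name=nm, length=float(blen * (0.5 + rng.random()))) for nm in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b], length=float(blen * (0.5 + rng.random()))))
    return nodes[0], names


def true_tree(config: SimulationConfig, rng: np.random.Generator) -> tuple[PhyloTree, dict[str, DomainClass]]:
    """The generating topology: ((((a1a, a1b), M2), M1), SOX, HMGB)-shaped.

    The alpha1 clade attaches inside the MATA_HMG subtree (between its
    two subclades), so MATA_HMG is paraphyletic without alpha1; SOX and
    HMGB branch off successively earlier.
    """
    n = config.n_per_class
    b_in = config.intra_branch_length
    stem = config.class_stem_length
    back = config.backbone_length
    a1a, ids_a1a = _random_clade("a1a_", n[DomainClass.ALPHA1_A], b_in, rng)
    a1b, ids_a1b = _random_clade("a1b_", n[DomainClass.ALPHA1_B], b_in, rng)
    n_mata = n[DomainClass.MATA_HMG]
    m1, ids_m1 = _random_clade("mataA_", n_mata - n_mata // 2, b_in, rng)
    m2, ids_m2 = _random_clade("mataB_", n_mata // 2, b_in, rng)
    sox, ids_sox = _random_clade("sox_", n[DomainClass.SOX], b_in, rng)
    hmgb, ids_hmgb = _random_clade("hmgb_", n[DomainClass.HMGB], b_in, rng)

    a1a.length = stem / 2.0
    a1b.length = stem / 2.0
    alpha1 = TreeNode(children=[a1a, a1b], length=stem)
    m2.length = stem / 2.0
    nest = TreeNode(children=[alpha1, m2], length=back)
    m1.length = stem / 2.0
    mata_group = TreeNode(children=[nest, m1], length=back)
    sox.length = stem
    inner = TreeNode(children=[mata_group, sox], length=back)
    hmgb.length = stem
    root = TreeNode(children=[inner, hmgb])
    class_of: dict[str, DomainClass] = {}
    for ids, cls in [
        (ids_a1a, DomainClass.ALPHA1_A),
        (ids_a1b, DomainClass.ALPHA1_B),
        (ids_m1, DomainClass.MATA_HMG),
        (ids_m2, DomainClass.MATA_HMG),
        (ids_sox, DomainClass.SOX),
        (ids_hmgb, DomainClass.HMGB),
    ]:
        for i in ids:
            class_of[i] = cls
    return PhyloTree(root), class_of


def make_domain_family_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Four-class dataset whose truth mirrors the inferred domain history."""
    rng = np.random.default_rng(config.seed)
    model = lg_model(alpha=config.alpha, n_categories=config.n_categories)
    tree, class_of = true_tree(config, rng)
    root_seq = sample_root(model.frequencies, config.core_length, rng)
    leaves, internals = evolve_on_tree(tree, root_seq, model, rng)
    cores_full = [
        DomainSequence(name, seq, domain_class=class_of[name])
        for name, seq in sorted(leaves.items())
    ]
    cores = apply_class_truncation(cores_full, config.truncation)
    # the truncations are terminal, so the true alignment pads them with
    # end gaps on the full core columns
    aln_rows = []
    for s_full, s_trunc in zip(cores_full, cores):
        pad = len(s_full.residues) - len(s_trunc.residues)
        aln_rows.append(s_trunc.residues + GAP * pad)
    true_alignment = Alignment([s.id for s in cores], aln_rows)
    if config.hmgb_insert_fraction > 0.0:
        cores = _add_hmgb_inserts(cores, config, model, rng)
    proteins, domain_end, motif_positions = build_full_proteins(cores, config, model, rng)
    truth = GroundTruth(
        tree=tree,
        newick=tree.to_newick(),
        ancestors=internals,
        motif_positions=motif_positions,
        class_of=class_of,
    )
    return SyntheticDataset(
        config=config,
        cores=cores,
        true_alignment=true_alignment,
        proteins=proteins,
        domain_end=domain_end,
        truth=truth,
    )


def _add_hmgb_inserts(
    cores: list[DomainSequence],
    config: SimulationConfig,
    model: RateModel,
    rng: np.random.Generator,
) -> list[DomainSequence]:
    """Give a fraction of HMGB rows a short interior insert block (the
    'small section of varying size' removed from real HMGB cores)."""
    out = []
    mid = config.core_length // 2
    for s in cores:
        if s.domain_class is DomainClass.HMGB and rng.random() < config.hmgb_insert_fraction:
            ins = sample_root(model.frequencies, config.hmgb_insert_length, rng)
            residues = s.residues[:mid] + ins + s.residues[mid:]
            out.append(DomainSequence(s.id, residues, taxon=s.taxon, domain_class=s.domain_class))
        else:
            out.append(s)
    return out


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit per-class FASTA, full proteins, truth newick/JSON and the
    tabular (id, class, sequence) file. Returns the paths written."""
    import json

    from .sequences import write_fasta, write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cls in DomainClass:
        members = ds.cores_by_class(cls)
        if not members:
            continue
        p = outdir / f"core_{cls.value.replace('-', '')}.fasta"
        write_fasta(members, p)
        paths[f"core_{cls.value}"] = p
    paths["cores_table"] = outdir / "cores.csv"
    write_table(ds.cores, paths["cores_table"])
    paths["proteins"] = outdir / "proteins.fasta"
    write_fasta(ds.proteins, paths["proteins"])
    paths["true_tree"] = outdir / "true_tree.nwk"
    paths["true_tree"].write_text(ds.truth.newick + "\n")
    paths["ground_truth"] = outdir / "ground_truth.json"
    payload = {
        "seed": ds.config.seed,
        "class_of": {k: v.value for k, v in ds.truth.class_of.items()},
        "ancestors": ds.truth.ancestors,
        "motif_positions": {k: list(v) for k, v in ds.truth.motif_positions.items()},
        "domain_end": ds.domain_end,
        "true_tree": ds.truth.newick,
    }
    paths["ground_truth"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths


# -- small fixed trees for calibration simulations -------------------------


def quartet_tree(internal_length: float, pendant_length: float = 0.1) -> PhyloTree:
    """((A,B),(C,D)) with a controllable internal edge (0 = star)."""
    ab = TreeNode(
        children=[TreeNode(name="A", length=pendant_length), TreeNode(name="B", length=pendant_length)],
        length=internal_length / 2.0,
    )
    cd = TreeNode(
        children=[TreeNode(name="C", length=pendant_length), TreeNode(name="D", length=pendant_length)],
        length=internal_length / 2.0,
    )
    return PhyloTree(TreeNode(children=[ab, cd]))


def balanced_tree(n_leaves: int, height: float, prefix: str = "t") -> PhyloTree:
    """Balanced bifurcating tree of total root-to-leaf height ``height``."""
    depth = int(np.ceil(np.log2(n_leaves)))
    if 2**depth != n_leaves:
        raise ValueError("n_leaves must be a power of two")
    blen = height / depth

    def build(level: int, start: int) -> TreeNode:
        if level == depth:
            return TreeNode(name=f"{prefix}{start}", length=blen)
        span = 2 ** (depth - level - 1)
        return TreeNode(
            children=[build(level + 1, start), build(level + 1, start + span)],
            length=blen if level > 0 else 0.0,
        )

    return PhyloTree(build(0, 0))
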