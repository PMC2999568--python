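"""Maximum-likelihood phylogenetics for protein domain alignments.

Implements Felsenstein's pruning algorithm under a reversible amino-acid
model with discrete-gamma rate mixing (and an optional invariant-site
spike), ML pairwise distances, a neighbor-joining starting tree, iterative
branch-length optimization, NNI hill-climbing, LR-ELW edge supports
estimated by RELL resampling over the NNI neighbourhood of each internal
edge, and the Kishino-Hasegawa / Shimodaira-Hasegawa topology tests.

Branch lengths are expected substitutions per site (at relative rate 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .models import RateModel
from .profiles import Alignment
from .sequences import AMINO_ACIDS
from .trees import PhyloTree, TreeNode

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 50.0
#: cap for saturated pairwise distances
MAX_PAIRWISE_DISTANCE = 10.0


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods of an alignment on a tree."""

    site_lnl: np.ndarray
    total: float

    def __post_init__(self) -> None:
        assert abs(self.site_lnl.sum() - self.total) < 1e-8


def encode_alignment(alignment: Alignment, alphabet: str = AMINO_ACIDS) -> dict[str, np.ndarray]:
    """Map each row to integer state codes; gaps and X become -1 (missing)."""
    index = {a: i for i, a in enumerate(alphabet)}
    out = {}
    for rid, row in zip(alignment.ids, alignment.rows):
        out[rid] = np.array([index.get(ch, -1) for ch in row], dtype=np.int64)
    return out


class PruningEngine:
    """Likelihood machinery bound to one (tree, alignment, model) triple.

    The tree is used in its rooted representation (root of degree 3 for an
    unrooted tree); under a reversible model the likelihood does not
    depend on the rooting. Partial likelihoods are kept per gamma category
    with per-(category, site) log-scaling to avoid underflow.

    ``down[i]`` is the classic inward partial of the subtree below node i;
    ``up[i]`` is the outward partial of the rest of the tree, evaluated at
    the parent end of the edge above i with the stationary frequencies
    folded in, so that the site likelihood factorizes through any single
    edge: L(s) = up[i] . (P(t_i) down[i]).
    """

    def __init__(self, tree: PhyloTree, alignment: Alignment, model: RateModel):
        leaf_names = set(tree.leaf_names())
        if leaf_names != set(alignment.ids):
            raise ValueError(
                "tree leaves and alignment rows differ: "
                f"only-tree={sorted(leaf_names - set(alignment.ids))[:4]} "
                f"only-alignment={sorted(set(alignment.ids) - leaf_names)[:4]}"
            )
        self.tree = tree
        self.model = model
        self.nodes: list[TreeNode] = list(tree.postorder())  # root last
        self._idx = {id(n): i for i, n in enumerate(self.nodes)}
        n_nodes = len(self.nodes)
        self.parent = np.full(n_nodes, -1, dtype=np.int64)
        self.children: list[list[int]] = [[] for _ in self.nodes]
        for i, n in enumerate(self.nodes):
            for c in n.children:
                ci = self._idx[id(c)]
                self.parent[ci] = i
                self.children[i].append(ci)
        self.root_idx = n_nodes - 1
        self.blen = np.array(
            [max(n.length, MIN_BRANCH_LENGTH) for n in self.nodes], dtype=float
        )
        self.rates = model.category_rates
        self.ncat = len(self.rates)
        self.pinv = model.p_invariant or 0.0

        codes = encode_alignment(alignment, model.alphabet)
        self.nsites = alignment.n_columns
        self.nstates = model.n_states
        shape = (self.ncat, self.nsites, self.nstates)
        self.down = np.ones((n_nodes,) + shape)
        self.down_logsc = np.zeros((n_nodes, self.ncat, self.nsites))
        self.up = np.ones((n_nodes,) + shape)
        self.up_logsc = np.zeros((n_nodes, self.ncat, self.nsites))
        self._trans = np.ones((n_nodes,) + shape)  # P_i @ down_i per edge
        self.is_leaf = np.zeros(n_nodes, dtype=bool)
        for i, n in enumerate(self.nodes):
            if n.is_leaf:
                self.is_leaf[i] = True
                code = codes[n.name]
                part = np.ones((self.nsites, self.nstates))
                known = code >= 0
                part[known] = 0.0
                part[np.where(known)[0], code[known]] = 1.0
                self.down[i] = part[None, :, :]
        # invariant-site likelihood: sum of pi over states consistent with
        # every non-missing leaf residue (0 for variable columns)
        compat = np.ones((self.nsites, self.nstates), dtype=bool)
        for i in np.where(self.is_leaf)[0]:
            compat &= self.down[int(i), 0] > 0.0
        self.invariant_lik = compat @ model.frequencies
        self._up_base: list[np.ndarray | None] = [None] * n_nodes
        self._up_base_log: list[np.ndarray | None] = [None] * n_nodes
        self._fresh = False

    # -- transition matrices ----------------------------------------------

    def _edge_P_all(self) -> np.ndarray:
        """(n_nodes, ncat, n, n) transition stacks for every edge at once."""
        m = self.model
        w = np.exp(
            m._eig_vals[None, None, :]
            * (self.blen[:, None, None] * self.rates[None, :, None])
        )
        P = np.einsum("ij,ecj,jk->ecik", m._eig_right, w, m._eig_left)
        return np.clip(P, 0.0, None)

    def _P_single(self, t: float) -> np.ndarray:
        return self.model.transition_probabilities_per_category(t)

    # -- passes -----------------------------------------------------------

    def compute_down(self) -> None:
        P_all = self._edge_P_all()
        for i in range(len(self.nodes)):
            if not self.is_leaf[i]:
                kids = self.children[i]
                part = self._trans[kids[0]].copy()
                logsc = self.down_logsc[kids[0]].copy()
                for ci in kids[1:]:
                    part *= self._trans[ci]
                    logsc += self.down_logsc[ci]
                m = part.max(axis=2)
                m = np.where(m > 0.0, m, 1.0)
                part /= m[:, :, None]
                logsc += np.log(m)
                self.down[i] = part
                self.down_logsc[i] = logsc
            if i != self.root_idx:
                # child contribution at the parent: P_i @ down_i
                np.matmul(self.down[i], P_all[i].transpose(0, 2, 1), out=self._trans[i])
        self._fresh = True

    def compute_up(self, targets: Sequence[int] | None = None) -> None:
        """Outward partials (requires a current ``compute_down``).

        ``targets`` restricts the pass to the nodes whose ``up`` is
        actually needed (and their ancestors), which makes optimizing a
        handful of edges much cheaper than a full pass.
        """
        needed: set[int] | None = None
        if targets is not None:
            needed = set()
            for t in targets:
                j = int(t)
                while j != -1:
                    needed.add(j)
                    j = int(self.parent[j])
        P_all = self._edge_P_all()
        pi = self.model.frequencies
        for i in reversed(range(len(self.nodes))):  # preorder
            if self.is_leaf[i] and i != self.root_idx:
                continue
            if needed is not None and i not in needed:
                continue
            if i == self.root_idx:
                base = np.broadcast_to(pi, (self.ncat, self.nsites, self.nstates))
                base_log = np.zeros((self.ncat, self.nsites))
            else:
                # transport up[i] through the edge above i (reverse direction)
                base = np.matmul(self.up[i], P_all[i])
                base_log = self.up_logsc[i]
            self._up_base[i] = base
            self._up_base_log[i] = base_log
            kids = self.children[i]
            for ci in kids:
                if needed is not None and ci not in needed:
                    continue
                part = base.copy()
                logsc = base_log.copy()
                for si in kids:
                    if si != ci:
                        part *= self._trans[si]
                        logsc = logsc + self.down_logsc[si]
                m = part.max(axis=2)
                m = np.where(m > 0.0, m, 1.0)
                part /= m[:, :, None]
                logsc += np.log(m)
                self.up[ci] = part
                self.up_logsc[ci] = logsc

    # -- likelihood -------------------------------------------------------

    def _mix_site_loglik(self, cat_lik: np.ndarray, cat_logsc: np.ndarray) -> np.ndarray:
        """Combine per-category site likelihoods into per-site lnL."""
        with np.errstate(divide="ignore"):
            logs = np.log(cat_lik) + cat_logsc  # (ncat, nsites)
        w_var = (1.0 - self.pinv) / self.ncat
        # hand-rolled logsumexp over the (small) category axis: hot path
        m = logs.max(axis=0)
        m = np.where(np.isfinite(m), m, 0.0)
        site = np.log(np.exp(logs - m).sum(axis=0) * w_var) + m
        if self.pinv > 0.0:
            with np.errstate(divide="ignore"):
                log_inv = np.log(self.pinv * self.invariant_lik)
            site = np.logaddexp(site, log_inv)
        return site

    def site_log_likelihoods(self) -> SiteLikelihoods:
        if not self._fresh:
            self.compute_down()
        root = self.down[self.root_idx]
        lik = root @ self.model.frequencies  # (ncat, nsites)
        site = self._mix_site_loglik(lik, self.down_logsc[self.root_idx])
        return SiteLikelihoods(site_lnl=site, total=float(site.sum()))

    def log_likelihood(self) -> float:
        return self.site_log_likelihoods().total

    # -- branch-length optimization ---------------------------------------

    def _edge_site_loglik(self, i: int, t: float) -> np.ndarray:
        P = self._P_single(t)
        tmp = np.matmul(self.up[i], P)  # (ncat, nsites, nstates)
        lik = np.einsum("csj,csj->cs", tmp, self.down[i])
        return self._mix_site_loglik(lik, self.down_logsc[i] + self.up_logsc[i])

    def edge_log_likelihood(self, i: int, t: float) -> float:
        return float(self._edge_site_loglik(i, t).sum())

    def optimize_edge(self, i: int, window: float = 0.0) -> None:
        """1-D optimization of the branch above node i against the current
        inward/outward partials.

        With ``window`` > 1 the search is bracketed around the current
        length (cheaper); if the optimum lands on the bracket edge the
        full range is searched instead.
        """
        f = lambda t: -self.edge_log_likelihood(i, t)
        t0 = self.blen[i]
        if window > 1.0:
            lo = max(MIN_BRANCH_LENGTH, t0 / window)
            hi = min(MAX_BRANCH_LENGTH, max(t0 * window, 1e-3))
        else:
            lo, hi = MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH
        res = minimize_scalar(f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-5})
        if window > 1.0 and (res.x < lo * 1.05 or res.x > hi * 0.95):
            full = minimize_scalar(
                f,
                bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                method="bounded",
                options={"xatol": 1e-5},
            )
            if full.fun < res.fun:
                res = full
        if res.fun <= f(t0):
            self.blen[i] = float(res.x)
            self.nodes[i].length = float(res.x)
            self._fresh = False

    def optimize_branch_lengths(
        self,
        tol: float = 1e-4,
        max_rounds: int = 10,
        edge_indices: Sequence[int] | None = None,
    ) -> tuple[float, bool]:
        """Sweeps of per-edge optimization until the lnL gain < ``tol``.

        Within a sweep every edge is optimized against the partials from
        the start of the sweep (a Jacobi-style update); the total lnL is
        re-evaluated after each sweep and a sweep that fails to improve
        it restores the previous lengths, so across sweeps the lnL is
        non-decreasing. Returns (lnL, converged).
        """
        if edge_indices is None:
            edge_indices = [i for i in range(len(self.nodes)) if i != self.root_idx]
        self.compute_down()
        last = self.site_log_likelihoods().total
        for _ in range(max_rounds):
            saved = self.blen.copy()
            self.compute_down()
            self.compute_up(targets=edge_indices if len(edge_indices) < len(self.nodes) // 2 else None)
            for i in edge_indices:
                self.optimize_edge(i, window=50.0)
            self.compute_down()
            lnl = self.site_log_likelihoods().total
            if lnl < last:
                self.blen = saved
                for i in edge_indices:
                    self.nodes[i].length = float(saved[i])
                self.compute_down()
                return last, True
            if lnl - last < tol:
                return lnl, True
            last = lnl
        return last, False

    def screen_nni(self, idx: int) -> tuple[float, float]:
        """Screened lnL of the two NNI rearrangements around edge ``idx``.

        Works entirely from cached inward/outward partials (requires
        current ``compute_down`` and a full ``compute_up``): subtrees keep
        their branch lengths and only the central edge is re-optimized,
        so each value is a lower bound on the candidate's fully optimized
        lnL. Candidate order matches ``_nni_neighbors_by_index``.
        """
        u = int(self.parent[idx])
        kids_u = [c for c in self.children[u] if c != idx]
        x1, x2 = self.children[idx]
        out = []
        for moved_out, kept in ((x1, x2), (x2, x1)):
            # candidate: sibling A joins `kept` below the edge; `moved_out`
            # replaces A above it
            a = kids_u[0]
            down = self._trans[kept] * self._trans[a]
            down_log = self.down_logsc[kept] + self.down_logsc[a]
            up = self._up_base[u] * self._trans[moved_out]
            up_log = self._up_base_log[u] + self.down_logsc[moved_out]
            for extra in kids_u[1:]:  # u is the (degree-3) root
                up = up * self._trans[extra]
                up_log = up_log + self.down_logsc[extra]
            logsc = down_log + up_log

            def neg(t: float) -> float:
                P = self._P_single(t)
                tmp = np.matmul(up, P)
                lik = np.einsum("csj,csj->cs", tmp, down)
                return -float(self._mix_site_loglik(lik, logsc).sum())

            res = minimize_scalar(
                neg,
                bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                method="bounded",
                options={"xatol": 1e-5},
            )
            out.append(-float(res.fun))
        return out[0], out[1]

    def sync_tree(self) -> PhyloTree:
        for i, n in enumerate(self.nodes):
            if i != self.root_idx:
                n.length = float(self.blen[i])
        return self.tree


# -- public operations ----------------------------------------------------


def log_likelihood(tree: PhyloTree, alignment: Alignment, model: RateModel) -> SiteLikelihoods:
    """Felsenstein-pruning log-likelihood of ``alignment`` on ``tree``."""
    return PruningEngine(tree, alignment, model).site_log_likelihoods()


def optimize_branch_lengths(
    tree: PhyloTree, alignment: Alignment, model: RateModel, tol: float = 1e-4
) -> tuple[PhyloTree, float]:
    engine = PruningEngine(tree.copy(), alignment, model)
    lnl, _ = engine.optimize_branch_lengths(tol=tol)
    return engine.sync_tree(), lnl


def optimize_branch_lengths_and_model(
    tree: PhyloTree,
    alignment: Alignment,
    model: RateModel,
    tol: float = 1e-4,
    max_rounds: int = 5,
) -> tuple[PhyloTree, RateModel, float]:
    """Alternate branch-length and rate-parameter (alpha, p_inv) optimization."""
    tree = tree.copy()
    engine = PruningEngine(tree, alignment, model)
    lnl, _ = engine.optimize_branch_lengths(tol=tol)
    tree = engine.sync_tree()
    for _ in range(max_rounds):
        improved = lnl
        if model.alpha is not None:
            # optimized on a log scale; the upper bound is high enough that
            # the discrete-gamma rates become effectively uniform, so the
            # +G family numerically nests the equal-rates model
            def neg_alpha(x: float) -> float:
                eng = PruningEngine(tree, alignment, model.with_params(alpha=float(np.exp(x))))
                return -eng.log_likelihood()

            res = minimize_scalar(
                neg_alpha,
                bounds=(np.log(0.02), np.log(1e6)),
                method="bounded",
                options={"xatol": 1e-3},
            )
            if -res.fun > lnl:
                model = model.with_params(alpha=float(np.exp(res.x)))
        if model.p_invariant is not None:

            def neg_pinv(p: float) -> float:
                eng = PruningEngine(tree, alignment, model.with_params(p_invariant=p))
                return -eng.log_likelihood()

            res = minimize_scalar(
                neg_pinv, bounds=(1e-6, 0.9), method="bounded", options={"xatol": 1e-4}
            )
            if -res.fun > lnl:
                model = model.with_params(p_invariant=float(res.x))
        engine = PruningEngine(tree, alignment, model)
        lnl, _ = engine.optimize_branch_lengths(tol=tol)
        tree = engine.sync_tree()
        if lnl - improved < max(tol, 1e-6):
            break
    return tree, model, lnl


def distance_matrix(
    alignment: Alignment,
    model: RateModel,
    cap: float = MAX_PAIRWISE_DISTANCE,
    refine: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Pairwise ML distances under ``model`` (saturated pairs capped).

    All pairs are scored on a common log-spaced grid of candidate
    distances (vectorized), then each pair's optimum is refined by
    bounded 1-D optimization between its grid neighbours.
    """
    if alignment.n_rows < 3:
        raise ValueError("need at least 3 rows")
    codes = encode_alignment(alignment, model.alphabet)
    ids = list(alignment.ids)
    n = len(ids)
    nstates = model.n_states
    pi = model.frequencies
    rates = model.category_rates

    import warnings

    pair_list = [(i, j) for i in range(n) for j in range(i + 1, n)]
    counts = np.zeros((len(pair_list), nstates * nstates))
    empty = np.zeros(len(pair_list), dtype=bool)
    for p, (i, j) in enumerate(pair_list):
        a, b = codes[ids[i]], codes[ids[j]]
        mask = (a >= 0) & (b >= 0)
        if not mask.any():
            empty[p] = True
            warnings.warn(
                f"no residue overlap between {ids[i]} and {ids[j]}; "
                f"distance set to the cap ({cap})"
            )
            continue
        cmat = np.zeros((nstates, nstates))
        np.add.at(cmat, (a[mask], b[mask]), 1.0)
        counts[p] = cmat.ravel()

    def log_m(t: float) -> np.ndarray:
        M = np.zeros((nstates, nstates))
        for r in rates:
            M += pi[:, None] * model.transition_probabilities(t, float(r))
        M /= len(rates)
        return np.log(np.maximum(M, 1e-300)).ravel()

    grid = np.geomspace(1e-4, cap, 48)
    scores = np.stack([counts @ log_m(t) for t in grid], axis=1)  # (npairs, ngrid)
    best = scores.argmax(axis=1)

    dmat = np.zeros((n, n))
    for p, (i, j) in enumerate(pair_list):
        if empty[p]:
            dmat[i, j] = dmat[j, i] = cap
            continue
        k = int(best[p])
        if refine and 0 < k < len(grid) - 1:
            row = counts[p]
            res = minimize_scalar(
                lambda t: -float(row @ log_m(t)),
                bounds=(grid[k - 1], grid[k + 1]),
                method="bounded",
                options={"xatol": 1e-6},
            )
            d = float(res.x)
        else:
            d = float(grid[k]) if k > 0 else MIN_BRANCH_LENGTH
        dmat[i, j] = dmat[j, i] = min(d, cap)
    return dmat, ids


def neighbor_joining(dmat: np.ndarray, ids: Sequence[str]) -> PhyloTree:
    """Standard NJ agglomeration (negative estimated lengths clamped to 0)."""
    import skbio

    dmat = np.asarray(dmat, dtype=float)
    if dmat.shape[0] != dmat.shape[1] or not np.allclose(dmat, dmat.T):
        raise ValueError("distance matrix must be square and symmetric")
    if dmat.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    sk = skbio.tree.nj(skbio.DistanceMatrix(dmat, ids=list(ids)))
    tree = PhyloTree.from_newick(str(sk))
    for _, child in tree.edges():
        child.length = max(child.length, 0.0)
    return tree.unrooted_copy()


def is_monophyletic(tree: PhyloTree, taxa: Sequence[str]) -> bool:
    """True iff an edge bipartition separates exactly ``taxa`` from the rest."""
    return tree.is_monophyletic(taxa)


# -- NNI search -----------------------------------------------------------


def _internal_edge_indices(engine: PruningEngine) -> list[int]:
    return [
        i
        for i, n in enumerate(engine.nodes)
        if i != engine.root_idx and not n.is_leaf
    ]


def _nni_neighbors_by_index(tree: PhyloTree, edge_postorder_idx: int) -> list[PhyloTree]:
    """The two NNI rearrangements around one internal edge.

    The edge is identified by the postorder index of its child node, so
    the operation commutes with ``PhyloTree.copy``.
    """
    neighbors = []
    for which in (0, 1):
        clone = tree.copy()
        nodes = list(clone.postorder())
        v = nodes[edge_postorder_idx]
        u = next(p for p in clone.root.preorder() if v in p.children)
        sibling = next(c for c in u.children if c is not v)
        x = v.children[which]
        u.children[u.children.index(sibling)] = x
        v.children[which] = sibling
        neighbors.append(PhyloTree(clone.root))
    return neighbors


def _local_edge_indices(engine: PruningEngine, center_idx: int) -> list[int]:
    """The rearranged edge plus its four adjacent edges."""
    local = {center_idx}
    local.update(engine.children[center_idx])
    p = int(engine.parent[center_idx])
    if p >= 0:
        if p != engine.root_idx:
            local.add(p)
        local.update(int(c) for c in engine.children[p] if c != center_idx)
    return sorted(i for i in local if i != engine.root_idx)


def nni_search(
    start: PhyloTree,
    alignment: Alignment,
    model: RateModel,
    tol: float = 1e-3,
    max_iter: int = 50,
) -> tuple[PhyloTree, float]:
    """Hill-climb over nearest-neighbour interchanges.

    Candidates are screened cheaply (re-optimizing only the rearranged
    edge); the best improving candidate is accepted and fully
    re-optimized, and the search terminates when no NNI improves the lnL
    by more than ``tol``. The returned lnL is never below the start lnL.
    """
    tree = start.copy().unrooted_copy()
    engine = PruningEngine(tree, alignment, model)
    lnl, _ = engine.optimize_branch_lengths()
    tree = engine.sync_tree()
    for _ in range(max_iter):
        engine.compute_down()
        engine.compute_up()
        best_move: tuple[int, int] | None = None
        best_lnl = lnl
        for idx in _internal_edge_indices(engine):
            for which, cand_lnl in enumerate(engine.screen_nni(idx)):
                if cand_lnl > best_lnl + tol:
                    best_lnl = cand_lnl
                    best_move = (idx, which)
        if best_move is None:
            break
        tree = _nni_neighbors_by_index(tree, best_move[0])[best_move[1]]
        engine = PruningEngine(tree, alignment, model)
        # light re-optimization between moves; full polish at the end
        new_lnl, _ = engine.optimize_branch_lengths(tol=max(tol, 1e-2), max_rounds=3)
        tree = engine.sync_tree()
        # the screened value is a lower bound of the re-optimized lnL
        lnl = max(new_lnl, best_lnl)
    engine = PruningEngine(tree, alignment, model)
    final_lnl, _ = engine.optimize_branch_lengths()
    return engine.sync_tree(), max(final_lnl, lnl)


# -- edge supports and topology tests --------------------------------------


@dataclass
class EdgeSupport:
    """LR-ELW support of one internal edge from its NNI neighbourhood."""

    edge_index: int
    bipartition: frozenset[str]
    weights_pct: np.ndarray  # (3,) ML topology first
    support: float


@dataclass
class EdgeSupportReport:
    supports: list[EdgeSupport]
    n_replicates: int
    seed: int
    tree: PhyloTree | None = None  # the input tree annotated with supports


def _rell_totals(site_lnl_matrix: np.ndarray, n_replicates: int, rng: np.random.Generator) -> np.ndarray:
    """(n_replicates, n_topologies) resampled totals from per-site lnL rows."""
    ntopo, nsites = site_lnl_matrix.shape
    counts = rng.multinomial(nsites, np.full(nsites, 1.0 / nsites), size=n_replicates)
    return counts @ site_lnl_matrix.T


def elw_edge_support(
    tree: PhyloTree,
    alignment: Alignment,
    model: RateModel,
    n_replicates: int = 10_000,
    seed: int = 0,
    edge_indices: Sequence[int] | None = None,
) -> EdgeSupportReport:
    """Expected-likelihood-weight support for internal edges.

    For each internal edge the three topologies of its NNI neighbourhood
    are compared by RELL: sites are resampled with replacement, per-site
    lnL vectors re-summed without re-optimization, and likelihood weights
    w_j = exp(lnL_j - max) / sum accumulated. The support is 100 x the
    mean weight of the ML topology. Supports are attached to the internal
    nodes of the returned (copied) tree. ``edge_indices`` restricts the
    computation to a subset of internal edges (postorder indices).
    """
    import warnings

    if n_replicates < 100:
        warnings.warn("fewer than 100 RELL replicates gives unstable supports")
    rng = np.random.default_rng(seed)
    tree = tree.copy().unrooted_copy()
    engine = PruningEngine(tree, alignment, model)
    base_sites = engine.site_log_likelihoods().site_lnl
    supports = []
    targets = list(edge_indices) if edge_indices is not None else _internal_edge_indices(engine)
    for idx in targets:
        rows = [base_sites]
        for cand in _nni_neighbors_by_index(tree, idx):
            cand_engine = PruningEngine(cand, alignment, model)
            local = _local_edge_indices(cand_engine, idx)
            cand_engine.optimize_branch_lengths(max_rounds=2, edge_indices=local)
            rows.append(cand_engine.site_log_likelihoods().site_lnl)
        mat = np.vstack(rows)
        totals = _rell_totals(mat, n_replicates, rng)
        shifted = totals - totals.max(axis=1, keepdims=True)
        w = np.exp(shifted)
        w /= w.sum(axis=1, keepdims=True)
        mean_w = 100.0 * w.mean(axis=0)
        node = engine.nodes[idx]
        node.support = float(mean_w[0])
        supports.append(
            EdgeSupport(
                edge_index=idx,
                bipartition=frozenset(node.leaf_names()),
                weights_pct=mean_w,
                support=float(mean_w[0]),
            )
        )
    return EdgeSupportReport(
        supports=supports, n_replicates=n_replicates, seed=seed, tree=tree
    )


@dataclass
class TopologyTestResult:
    index: int
    log_likelihood: float
    delta_lnl: float
    kh_p: float
    sh_p: float
    is_best: bool


def kh_sh_test(
    topologies: Sequence[PhyloTree],
    alignment: Alignment,
    model: RateModel,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> list[TopologyTestResult]:
    """RELL-based KH (pairwise vs best, two-sided) and SH p-values.

    Branch lengths of every candidate topology are re-optimized before
    the per-site lnL vectors are taken. The ML topology receives p = 1
    under both tests by construction.
    """
    if len(topologies) < 2:
        raise ValueError("need at least two candidate topologies")
    rng = np.random.default_rng(seed)
    site_rows = []
    for top in topologies:
        engine = PruningEngine(top.copy().unrooted_copy(), alignment, model)
        engine.optimize_branch_lengths()
        site_rows.append(engine.site_log_likelihoods().site_lnl)
    mat = np.vstack(site_rows)
    totals = mat.sum(axis=1)
    best = int(np.argmax(totals))
    R = _rell_totals(mat, n_replicates, rng)  # (nrep, ntopo)
    results = []
    centered = R - R.mean(axis=0, keepdims=True)
    for j in range(len(topologies)):
        delta = totals[best] - totals[j]
        d_star = centered[:, best] - centered[:, j]
        kh_p = float(np.mean(np.abs(d_star) >= delta))
        sh_null = centered.max(axis=1) - centered[:, j]
        sh_p = float(np.mean(sh_null >= delta))
        results.append(
            TopologyTestResult(
                index=j,
                log_likelihood=float(totals[j]),
                delta_lnl=float(delta),
                kh_p=kh_p,
                sh_p=sh_p,
                is_best=(j == best),
            )
        )
    return results
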