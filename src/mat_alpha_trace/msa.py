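"""Pairwise and progressive protein alignment (affine gaps, BLOSUM62).

A deliberately compact progressive aligner: pairwise Gotoh alignment
(global and local), a UPGMA guide tree on fractional shared-k-mer
distances, and profile-profile global alignment up the guide tree. It
stands where a production pipeline would call an external aligner, and
externally aligned FASTA is accepted everywhere an alignment is needed.

Gap scoring convention: a gap run of length L scores
``gap_open + (L - 1) * gap_extend`` (both scores are negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage

from .profiles import Alignment
from .sequences import AMINO_ACIDS, GAP, DomainSequence, UnknownResidueError, check_unique_ids
from .trees import PhyloTree, TreeNode

NEG_INF = float("-inf")
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def blosum62() -> dict[tuple[str, str], float]:
    """The BLOSUM62 scoring table as a plain pair-keyed dict."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    table = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0


@dataclass
class PairwiseAlignment:
    score: float
    aligned_a: str
    aligned_b: str
    #: 1-based start of the aligned segment in each input (local mode)
    start_a: int = 1
    start_b: int = 1
    mode: str = "global"


def _check_matrix(seqs: Sequence[str], matrix: dict) -> None:
    known = {a for a, _ in matrix}
    for s in seqs:
        missing = set(s) - known
        if missing:
            raise UnknownResidueError(
                f"residues with no scoring-matrix entry: {sorted(missing)}"
            )


def pairwise_align(
    a: str,
    b: str,
    matrix: dict | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    mode: str = "global",
) -> PairwiseAlignment:
    """Optimal affine-gap alignment of two residue strings (Gotoh).

    ``mode="global"`` aligns the full sequences; ``mode="local"`` returns
    the maximal-scoring segment pair (score 0 and empty strings when no
    positive-scoring pair exists).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    matrix = matrix if matrix is not None else blosum62()
    a, b = a.upper(), b.upper()
    _check_matrix([a, b], matrix)
    n, m = len(a), len(b)
    local = mode == "local"

    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in a (consumes b)
    M[0, 0] = 0.0
    ptr_M = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=M,1=X,2=Y,3=local start
    ptr_X = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_Y = np.zeros((n + 1, m + 1), dtype=np.int8)
    if not local:
        for i in range(1, n + 1):
            X[i, 0] = gap_open + (i - 1) * gap_extend
            ptr_X[i, 0] = 0 if i == 1 else 1
        for j in range(1, m + 1):
            Y[0, j] = gap_open + (j - 1) * gap_extend
            ptr_Y[0, j] = 0 if j == 1 else 2
    else:
        M[:, 0] = 0.0
        M[0, :] = 0.0

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[(a[i - 1], b[j - 1])]
            opts = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(opts))
            best = opts[k] + s
            if local and best < 0.0:
                best, k = 0.0, 3
            M[i, j] = best
            ptr_M[i, j] = k

            opts = (M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend, Y[i - 1, j] + gap_open)
            k = int(np.argmax(opts))
            X[i, j] = opts[k]
            ptr_X[i, j] = k

            opts = (M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend, X[i, j - 1] + gap_open)
            k = int(np.argmax(opts))
            # encode the Y-state predecessors in the same 0=M,1=X,2=Y scheme
            Y[i, j] = opts[k]
            ptr_Y[i, j] = (0, 2, 1)[k]

    out_a: list[str] = []
    out_b: list[str] = []
    if local:
        i, j = (int(x) for x in np.unravel_index(int(np.argmax(M)), M.shape))
        if M[i, j] <= 0.0:
            return PairwiseAlignment(0.0, "", "", 0, 0, mode="local")
        score = float(M[i, j])
        state = 0
        while True:
            if state == 0:
                if M[i, j] == 0.0:
                    break
                prev = ptr_M[i, j]
                out_a.append(a[i - 1]); out_b.append(b[j - 1])
                i, j = i - 1, j - 1
                if prev == 3:
                    break
                state = prev
            elif state == 1:
                state = ptr_X[i, j]
                out_a.append(a[i - 1]); out_b.append(GAP)
                i -= 1
            else:
                state = ptr_Y[i, j]
                out_a.append(GAP); out_b.append(b[j - 1])
                j -= 1
        return PairwiseAlignment(
            score, "".join(reversed(out_a)), "".join(reversed(out_b)),
            start_a=i + 1, start_b=j + 1, mode="local",
        )

    ends = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(ends))
    score = float(ends[state])
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            state = ptr_M[i, j]
            out_a.append(a[i - 1]); out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            state = ptr_X[i, j]
            out_a.append(a[i - 1]); out_b.append(GAP)
            i -= 1
        else:
            state = ptr_Y[i, j]
            out_a.append(GAP); out_b.append(b[j - 1])
            j -= 1
    return PairwiseAlignment(score, "".join(reversed(out_a)), "".join(reversed(out_b)))


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - fraction of shared k-mers (relative to the smaller k-mer set)."""
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def build_guide_tree(seqs: Sequence[DomainSequence], k: int = 3) -> PhyloTree:
    """UPGMA guide tree on fractional shared-k-mer distances."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    check_unique_ids(seqs)
    n = len(seqs)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(kmer_distance(seqs[i].residues, seqs[j].residues, k))
    Z = linkage(np.array(condensed), method="average")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=s.id) for i, s in enumerate(seqs)
    }
    heights = {i: 0.0 for i in range(n)}
    for step, (ia, ib, dist, _) in enumerate(Z):
        ia, ib = int(ia), int(ib)
        h = float(dist) / 2.0
        left, right = nodes.pop(ia), nodes.pop(ib)
        left.length = h - heights[ia]
        right.length = h - heights[ib]
        idx = n + step
        nodes[idx] = TreeNode(children=[left, right])
        heights[idx] = h
    root = nodes.popitem()[1]
    return PhyloTree(root)


# -- profile-profile progressive alignment ---------------------------------


def _profile_counts(alignment: Alignment) -> np.ndarray:
    """(ncol, 20) residue frequencies relative to total row count.

    Gap (and X) rows contribute nothing, so gappy columns carry less
    weight in the column-pair score.
    """
    ncol = alignment.n_columns
    counts = np.zeros((ncol, 20))
    for row in alignment.rows:
        for c, ch in enumerate(row):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[c, idx] += 1
    return counts / max(alignment.n_rows, 1)


def _matrix_array(matrix: dict) -> np.ndarray:
    arr = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            arr[i, j] = matrix[(a, b)]
    return arr


def _align_profiles(
    left: Alignment,
    right: Alignment,
    smat: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> Alignment:
    """Global affine-gap alignment of two alignments (profile columns)."""
    fa = _profile_counts(left)
    fb = _profile_counts(right)
    S = fa @ smat @ fb.T  # (ncolA, ncolB) expected column-pair scores
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    ptr_M = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_X = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_Y = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        ptr_X[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        ptr_Y[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        Mi1 = M[i - 1]; Xi1 = X[i - 1]; Yi1 = Y[i - 1]
        for j in range(1, m + 1):
            opts = (Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            k = int(np.argmax(opts))
            M[i, j] = opts[k] + S[i - 1, j - 1]
            ptr_M[i, j] = k
            opts = (Mi1[j] + gap_open, Xi1[j] + gap_extend, Yi1[j] + gap_open)
            k = int(np.argmax(opts))
            X[i, j] = opts[k]
            ptr_X[i, j] = k
            opts = (M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend, X[i, j - 1] + gap_open)
            k = int(np.argmax(opts))
            Y[i, j] = opts[k]
            ptr_Y[i, j] = (0, 2, 1)[k]
    state = int(np.argmax((M[n, m], X[n, m], Y[n, m])))
    i, j = n, m
    cols: list[tuple[int, int]] = []  # (colA or -1, colB or -1)
    while i > 0 or j > 0:
        if state == 0:
            state = ptr_M[i, j]
            cols.append((i - 1, j - 1)); i -= 1; j -= 1
        elif state == 1:
            state = ptr_X[i, j]
            cols.append((i - 1, -1)); i -= 1
        else:
            state = ptr_Y[i, j]
            cols.append((-1, j - 1)); j -= 1
    cols.reverse()
    rows = []
    for row in left.rows:
        rows.append("".join(row[ca] if ca >= 0 else GAP for ca, _ in cols))
    for row in right.rows:
        rows.append("".join(row[cb] if cb >= 0 else GAP for _, cb in cols))
    return Alignment(left.ids + right.ids, rows)


def progressive_align(
    seqs: Sequence[DomainSequence],
    guide: PhyloTree | None = None,
    matrix: dict | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Profile-profile global alignment up a guide tree.

    Row order matches the input order; ungapping any row recovers its
    source sequence exactly.
    """
    if not seqs:
        raise ValueError("no sequences")
    check_unique_ids(seqs)
    if len(seqs) == 1:
        return Alignment([seqs[0].id], [seqs[0].residues])
    matrix = matrix if matrix is not None else blosum62()
    _check_matrix([s.residues.replace("X", "") for s in seqs], matrix)
    if guide is None:
        guide = build_guide_tree(seqs)
    if set(guide.leaf_names()) != {s.id for s in seqs}:
        raise ValueError("guide tree leaves do not match sequence ids")
    smat = _matrix_array(matrix)
    by_id = {s.id: s for s in seqs}

    def build(node: TreeNode) -> Alignment:
        if node.is_leaf:
            s = by_id[node.name]
            return Alignment([s.id], [s.residues])
        sub = build(node.children[0])
        for child in node.children[1:]:
            sub = _align_profiles(sub, build(child), smat, gap_open, gap_extend)
        return sub

    aligned = build(guide.root)
    order = {s.id: i for i, s in enumerate(seqs)}
    pairs = sorted(zip(aligned.ids, aligned.rows), key=lambda p: order[p[0]])
    return Alignment([p[0] for p in pairs], [p[1] for p in pairs])
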