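"""Pairwise and progressive aligner against brute-force enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mat_alpha_trace.msa import (
    build_guide_tree,
    kmer_distance,
    pairwise_align,
    progressive_align,
)
from mat_alpha_trace.sequences import AMINO_ACIDS, DomainSequence, UnknownResidueError


def brute_force_global(a, b, matrix, gap_open, gap_extend):
    """Exhaustive enumeration of all affine-gap global alignments.

    Independent of the DP: recursively emits every gapped string pair and
    scores it (gap run of length L costs open + (L-1)*extend).
    """

    def score(pairs):
        total, prev = 0.0, None
        for x, y in pairs:
            if x == "-":
                total += gap_extend if prev == "a" else gap_open
                prev = "a"
            elif y == "-":
                total += gap_extend if prev == "b" else gap_open
                prev = "b"
            else:
                total += matrix[(x, y)]
                prev = None
        return total

    best = [float("-inf")]

    def rec(i, j, pairs):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score(pairs))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, pairs + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, pairs + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, pairs + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


class TestPairwise:
    def test_identity_alignment_scores_diagonal_sum(self, b62):
        aln = pairwise_align("ACDEF", "ACDEF", b62)
        assert aln.aligned_a == aln.aligned_b == "ACDEF"
        assert aln.score == sum(b62[(c, c)] for c in "ACDEF")

    def test_empty_input_rejected(self, b62):
        with pytest.raises(ValueError):
            pairwise_align("AC", "", b62)
        with pytest.raises(ValueError):
            pairwise_align("", "AC", b62)

    def test_unknown_residue_rejected(self):
        with pytest.raises(UnknownResidueError):
            pairwise_align("AC", "AB", {("A", "A"): 1.0, ("C", "C"): 1.0})

    def test_global_matches_bruteforce_on_short_peptides(self, b62):
        """All pairs of length <= 3 over {A, C, D} against enumeration."""
        alphabet = "ACD"
        words = [
            "".join(w)
            for n in (1, 2, 3)
            for w in itertools.product(alphabet, repeat=n)
        ]
        for a in words:
            for b in words:
                expected = brute_force_global(a, b, b62, -11.0, -1.0)
                got = pairwise_align(a, b, b62).score
                assert got == pytest.approx(expected), (a, b)

    def test_global_matches_bruteforce_on_sampled_4mers(self, b62):
        rng = np.random.default_rng(42)
        alphabet = np.array(list("ACD"))
        for _ in range(60):
            a = "".join(rng.choice(alphabet, size=4))
            b = "".join(rng.choice(alphabet, size=4))
            expected = brute_force_global(a, b, b62, -11.0, -1.0)
            assert pairwise_align(a, b, b62).score == pytest.approx(expected), (a, b)

    def test_local_dominates_global(self, b62):
        """The optimal local score is never below the global score."""
        rng = np.random.default_rng(7)
        aas = np.array(list(AMINO_ACIDS))
        for _ in range(25):
            a = "".join(rng.choice(aas, size=int(rng.integers(3, 12))))
            b = "".join(rng.choice(aas, size=int(rng.integers(3, 12))))
            g = pairwise_align(a, b, b62, mode="global").score
            l = pairwise_align(a, b, b62, mode="local").score
            assert l >= g - 1e-9

    def test_local_extracts_shared_segment(self, b62):
        aln = pairwise_align("PPPACDEFPPP", "GGGACDEFGGG", b62, mode="local")
        assert aln.aligned_a == aln.aligned_b == "ACDEF"
        assert (aln.start_a, aln.start_b) == (4, 4)


class TestGuideTree:
    def test_two_sequences_form_cherry_with_equal_pendants(self):
        seqs = [DomainSequence("x", "ACDEFGH"), DomainSequence("y", "ACDWFGH")]
        tree = build_guide_tree(seqs)
        kids = tree.root.children
        assert sorted(tree.leaf_names()) == ["x", "y"]
        assert kids[0].length == pytest.approx(kids[1].length)

    def test_identical_sequences_join_first(self):
        seqs = [
            DomainSequence("a", "ACDEFGHIKL"),
            DomainSequence("b", "WWYYPPGGMM"),
            DomainSequence("c", "ACDEFGHIKL"),
        ]
        tree = build_guide_tree(seqs)
        assert tree.is_monophyletic({"a", "c"})

    def test_upgma_joins_minimal_pair_first(self):
        # hand-computed k=2 shared-k-mer distances: p/q share all 2-mers,
        # r shares half with p/q, s shares none
        seqs = [
            DomainSequence("p", "ACACA"),
            DomainSequence("q", "CACAC"),
            DomainSequence("r", "ACDEF"),
            DomainSequence("s", "WYWYW"),
        ]
        assert kmer_distance("ACACA", "CACAC", 2) == pytest.approx(0.0)
        assert kmer_distance("ACACA", "WYWYW", 2) == pytest.approx(1.0)
        tree = build_guide_tree(seqs, k=2)
        assert tree.is_monophyletic({"p", "q"})

    def test_duplicate_ids_rejected(self):
        seqs = [DomainSequence("a", "ACDEF"), DomainSequence("a", "ACDEW")]
        with pytest.raises(ValueError):
            build_guide_tree(seqs)


class TestProgressive:
    def test_identical_sequences_align_without_gaps(self):
        seqs = [DomainSequence(f"s{i}", "MKVLANWE") for i in range(4)]
        aln = progressive_align(seqs)
        assert aln.n_columns == 8
        assert all("-" not in row for row in aln.rows)

    def test_single_sequence_returns_itself(self):
        aln = progressive_align([DomainSequence("only", "MKVLA")])
        assert aln.ids == ["only"] and aln.rows == ["MKVLA"]

    def test_internal_deletion_gets_gap_at_deleted_position(self):
        full = "MKWRPTCDEF"
        deleted = full[:4] + full[5:]  # drop the P at position 5
        seqs = [
            DomainSequence("a", full),
            DomainSequence("b", full),
            DomainSequence("c", deleted),
        ]
        aln = progressive_align(seqs)
        assert aln.n_columns == len(full)
        assert aln.row("c")[4] == "-"
        assert aln.row("a") == full

    def test_row_order_matches_input_order(self):
        seqs = [
            DomainSequence("z", "ACDEFGHIKL"),
            DomainSequence("a", "ACDEFGHIKL"),
            DomainSequence("m", "ACDWFGHIKL"),
        ]
        assert progressive_align(seqs).ids == ["z", "a", "m"]

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.text(alphabet="ACDEFGHIKL", min_size=3, max_size=10),
            min_size=2,
            max_size=5,
        )
    )
    def test_ungapping_rows_roundtrips_inputs(self, raw):
        seqs = [DomainSequence(f"s{i}", r) for i, r in enumerate(raw)]
        aln = progressive_align(seqs)
        for s in seqs:
            assert aln.ungapped(s.id) == s.residues
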