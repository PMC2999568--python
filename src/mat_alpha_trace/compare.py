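"""BLAST-style scoring of consensus (and ancestral) sequence similarity.

Two consensus core sequences are compared by optimal local affine-gap
alignment under BLOSUM62; the result is reported the way BLASTP reports
a hit: percent identity, percent positives (aligned pairs with a positive
matrix score), bit score and a Karlin-Altschul expect value
E = K * m * n * exp(-lambda * S).

The default lambda/K are the standard gapped BLOSUM62 constants; with the
pairwise search space (m, n = the two sequence lengths) the E-values are
order-of-magnitude indicators, not database-search statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import pandas as pd

from .msa import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, blosum62, pairwise_align
from .profiles import ConsensusSequence
from .sequences import GAP

#: gapped BLOSUM62 Karlin-Altschul parameters (BLAST defaults)
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass
class ComparisonResult:
    query_id: str
    subject_id: str
    alignment_length: int
    n_identical: int
    n_positive: int
    raw_score: float
    bit_score: float
    e_value: float
    m: int
    n: int
    aligned_query: str = ""
    aligned_subject: str = ""
    no_significant_alignment: bool = False

    @property
    def identity_pct(self) -> float:
        if self.alignment_length == 0:
            return 0.0
        return 100.0 * self.n_identical / self.alignment_length

    @property
    def positives_pct(self) -> float:
        if self.alignment_length == 0:
            return 0.0
        return 100.0 * self.n_positive / self.alignment_length


def karlin_altschul_evalue(
    raw_score: float,
    m: int,
    n: int,
    lambda_: float = DEFAULT_LAMBDA,
    k_const: float = DEFAULT_K,
) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    return k_const * m * n * math.exp(-lambda_ * raw_score)


def compare_consensus(
    c1: ConsensusSequence | str,
    c2: ConsensusSequence | str,
    matrix: dict | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    lambda_: float = DEFAULT_LAMBDA,
    k_const: float = DEFAULT_K,
    m: int | None = None,
    n: int | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> ComparisonResult:
    """Local alignment of two consensus sequences with BLAST-style statistics.

    Identity counts aligned identical residue pairs; positives count
    aligned pairs with matrix score > 0 (identical pairs included);
    both are relative to the alignment length (gap columns included).
    """
    s1 = c1.residues if isinstance(c1, ConsensusSequence) else c1
    s2 = c2.residues if isinstance(c2, ConsensusSequence) else c2
    if isinstance(c1, ConsensusSequence) and c1.source_class:
        query_id = c1.source_class
    if isinstance(c2, ConsensusSequence) and c2.source_class:
        subject_id = c2.source_class
    if not s1 or not s2:
        raise ValueError("consensus sequences must be non-empty")
    matrix = matrix if matrix is not None else blosum62()
    m = m if m is not None else len(s1)
    n = n if n is not None else len(s2)
    # align in a canonical orientation so results are exactly symmetric in
    # query/subject even when the optimal local alignment is not unique
    if s2 < s1:
        aln = pairwise_align(s2, s1, matrix, gap_open, gap_extend, mode="local")
        aln = type(aln)(
            score=aln.score,
            aligned_a=aln.aligned_b,
            aligned_b=aln.aligned_a,
            start_a=aln.start_b,
            start_b=aln.start_a,
            mode=aln.mode,
        )
    else:
        aln = pairwise_align(s1, s2, matrix, gap_open, gap_extend, mode="local")
    length = len(aln.aligned_a)
    n_ident = n_pos = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == GAP or y == GAP:
            continue
        if x == y:
            n_ident += 1
        if matrix[(x, y)] > 0:
            n_pos += 1
    bit = (lambda_ * aln.score - math.log(k_const)) / math.log(2.0)
    return ComparisonResult(
        query_id=query_id,
        subject_id=subject_id,
        alignment_length=length,
        n_identical=n_ident,
        n_positive=n_pos,
        raw_score=aln.score,
        bit_score=bit,
        e_value=karlin_altschul_evalue(aln.score, m, n, lambda_, k_const),
        m=m,
        n=n,
        aligned_query=aln.aligned_a,
        aligned_subject=aln.aligned_b,
        no_significant_alignment=(length == 0),
    )


def all_pairs_comparison(
    consensuses: Sequence[ConsensusSequence], **params
) -> list[ComparisonResult]:
    """One comparison per unordered pair of consensus sequences."""
    if len(consensuses) < 2:
        raise ValueError("need at least two consensus sequences")
    results = []
    for i, j in combinations(range(len(consensuses)), 2):
        ci, cj = consensuses[i], consensuses[j]
        results.append(
            compare_consensus(
                ci,
                cj,
                query_id=ci.source_class or f"consensus_{i}",
                subject_id=cj.source_class or f"consensus_{j}",
                **params,
            )
        )
    return results


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """BLAST-tabular-style summary (qid, sid, pident, ppos, length, bitscore, evalue)."""
    return pd.DataFrame(
        {
            "qid": [r.query_id for r in results],
            "sid": [r.subject_id for r in results],
            "pident": [round(r.identity_pct, 2) for r in results],
            "ppos": [round(r.positives_pct, 2) for r in results],
            "length": [r.alignment_length for r in results],
            "bitscore": [round(r.bit_score, 2) for r in results],
            "evalue": [r.e_value for r in results],
        }
    )


def write_comparison_tsv(results: Sequence[ComparisonResult], path: str | Path) -> None:
    comparison_table(results).to_csv(path, sep="\t", index=False)
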