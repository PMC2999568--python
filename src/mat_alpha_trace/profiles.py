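"""Core-region extraction, coverage filtering and positional profiles.

Implements the profiling stages of the domain-family comparison: restrict
an alignment to the ~40-column conserved core anchored on a reference row,
drop rows covering less than a fraction of the core, delete minority
insert columns, and summarize the result as per-column amino-acid
frequencies, information content (bits) and a consensus sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequences import AMINO_ACIDS, GAP, MISSING_RESIDUES, DomainSequence

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
MAX_IC_BITS = math.log2(len(AMINO_ACIDS))


@dataclass
class Alignment:
    """A gapped residue matrix: ordered (id, gapped string) rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids in alignment")
        if self.rows:
            ncol = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != ncol:
                    raise ValueError(f"row {rid} has length {len(row)} != {ncol}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise KeyError(f"no row with id {rid!r}") from None

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def select_columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment(list(self.ids), ["".join(r[c] for c in cols) for r in self.rows])

    def select_rows(self, keep_ids: Sequence[str]) -> "Alignment":
        keep = set(keep_ids)
        pairs = [(i, r) for i, r in zip(self.ids, self.rows) if i in keep]
        return Alignment([p[0] for p in pairs], [p[1] for p in pairs])

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)

    @classmethod
    def from_sequences(cls, seqs: Iterable[DomainSequence]) -> "Alignment":
        """Trivial alignment of already equal-length (gap-free) sequences."""
        seqs = list(seqs)
        return cls([s.id for s in seqs], [s.residues for s in seqs])


@dataclass
class PositionProfile:
    """Per-column amino-acid frequencies and information content.

    ``frequencies`` is (n_columns, 20) over the alphabet ``ACDEFGHIKLMNPQRSTVWY``;
    gaps and unknown residues are excluded from the denominators.
    Information content per column is log2(20) minus the Shannon entropy of
    the frequency vector, in bits.
    """

    frequencies: np.ndarray
    counts: np.ndarray
    information_bits: np.ndarray
    n_sequences: int
    pseudocount: float
    all_gap_columns: list[int] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.frequencies.shape[0]


@dataclass
class ConsensusSequence:
    """Modal residue per profile column with its support fraction."""

    residues: str
    support: np.ndarray
    source_class: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def extract_core(alignment: Alignment, anchor_row: str, start: int, end: int) -> Alignment:
    """Restrict an alignment to the columns spanned by an anchor window.

    ``start``/``end`` are 1-based inclusive positions in the *ungapped*
    anchor row. Insertion columns (gaps in the anchor) interior to the
    window are retained; they can be dropped later with
    :func:`remove_gappy_columns`.
    """
    row = alignment.row(anchor_row)
    n_res = len(row) - row.count(GAP)
    if not (1 <= start <= end <= n_res):
        raise ValueError(
            f"window {start}-{end} outside anchor row {anchor_row!r} (length {n_res})"
        )
    pos = 0
    first = last = None
    for col, ch in enumerate(row):
        if ch != GAP:
            pos += 1
            if pos == start:
                first = col
            if pos == end:
                last = col
                break
    assert first is not None and last is not None
    return alignment.select_columns(range(first, last + 1))


def coverage_filter(
    alignment: Alignment, min_coverage: float = 0.8, core_length: int | None = None
) -> tuple[Alignment, list[str]]:
    """Drop rows covering less than ``min_coverage`` of the core.

    Coverage is the row's non-gap (and non-X) residue count within the
    alignment divided by ``core_length`` (defaults to the column count).
    Rows exactly at the threshold are kept: the rule removes rows with
    *less than* the required coverage.
    """
    if alignment.n_rows == 0:
        raise ValueError("empty alignment")
    if not (0.0 < min_coverage <= 1.0):
        raise ValueError("min_coverage must be in (0, 1]")
    core_length = core_length or alignment.n_columns
    removed = []
    for rid, row in zip(alignment.ids, alignment.rows):
        n_res = sum(1 for ch in row if ch != GAP and ch not in MISSING_RESIDUES)
        if n_res / core_length < min_coverage:
            removed.append(rid)
    kept = [i for i in alignment.ids if i not in set(removed)]
    return alignment.select_rows(kept), removed


def remove_gappy_columns(alignment: Alignment, max_gap_fraction: float = 0.5) -> Alignment:
    """Delete columns whose gap fraction exceeds ``max_gap_fraction``."""
    if not (0.0 <= max_gap_fraction < 1.0):
        raise ValueError("max_gap_fraction must be in [0, 1)")
    if alignment.n_rows == 0:
        return alignment
    keep = []
    for c in range(alignment.n_columns):
        gaps = sum(1 for r in alignment.rows if r[c] == GAP)
        if gaps / alignment.n_rows <= max_gap_fraction:
            keep.append(c)
    return alignment.select_columns(keep)


def column_frequencies(alignment: Alignment, pseudocount: float = 0.0) -> PositionProfile:
    """Per-column residue frequencies and information content.

    Frequencies are (count + pseudocount) / (non-gap total + 20 * pseudocount).
    A column that is entirely gaps (or X) gets uniform frequencies,
    information content 0, and is flagged in ``all_gap_columns``.
    """
    if alignment.n_rows == 0:
        raise ValueError("empty alignment")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    ncol = alignment.n_columns
    counts = np.zeros((ncol, 20))
    for row in alignment.rows:
        for c, ch in enumerate(row):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[c, idx] += 1
    totals = counts.sum(axis=1)
    all_gap = [c for c in range(ncol) if totals[c] == 0]
    freqs = np.empty_like(counts)
    for c in range(ncol):
        if totals[c] == 0:
            freqs[c] = 1.0 / 20.0
        else:
            freqs[c] = (counts[c] + pseudocount) / (totals[c] + 20.0 * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = MAX_IC_BITS + plogp.sum(axis=1)
    ic[all_gap] = 0.0
    ic = np.clip(ic, 0.0, MAX_IC_BITS)
    return PositionProfile(
        frequencies=freqs,
        counts=counts,
        information_bits=ic,
        n_sequences=alignment.n_rows,
        pseudocount=pseudocount,
        all_gap_columns=all_gap,
    )


def consensus(profile: PositionProfile, source_class: str = "") -> ConsensusSequence:
    """Modal residue per column; ties broken alphabetically."""
    if profile.n_columns == 0:
        raise ValueError("empty profile")
    # argmax returns the first (alphabetically smallest) index on ties
    # because the alphabet string is sorted
    best = profile.frequencies.argmax(axis=1)
    residues = "".join(AMINO_ACIDS[i] for i in best)
    support = profile.frequencies[np.arange(profile.n_columns), best]
    return ConsensusSequence(residues=residues, support=support, source_class=source_class)


def profile_table(profile: PositionProfile, cons: ConsensusSequence | None = None) -> pd.DataFrame:
    """Tabular profile: column index (1-based), 20 frequencies, IC, consensus."""
    cons = cons or consensus(profile)
    df = pd.DataFrame(profile.frequencies, columns=list(AMINO_ACIDS))
    df.insert(0, "column", np.arange(1, profile.n_columns + 1))
    df["ic_bits"] = profile.information_bits
    df["consensus"] = list(cons.residues)
    df["support"] = cons.support
    return df


def write_profile_tsv(profile: PositionProfile, path: str | Path, cons: ConsensusSequence | None = None) -> None:
    profile_table(profile, cons).to_csv(path, sep="\t", index=False, float_format="%.6g")
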