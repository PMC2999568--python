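"""PROSITE-style pattern parsing and scanning.

Supports the deterministic PROSITE subset needed for the conserved
region downstream of the fungal alpha1 domain — the core pattern
``Y-[LMIF]-x(3)-G-[WL]`` — plus negated sets and bounded wildcard
repeats: literals, ``[sets]``, ``{negated}``, ``x``, ``x(n)`` and
``x(n,m)``. Positions are 1-based, matching ScanProsite output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sequences import AMINO_ACIDS, DomainSequence

#: the conserved core motif downstream of the alpha1 domain
ALPHA1_DOWNSTREAM_CORE = "Y-[LMIF]-x(3)-G-[WL]"
#: length of the conserved downstream region scanned for the motif
DOWNSTREAM_WINDOW = 60


class PatternSyntaxError(ValueError):
    """Malformed PROSITE pattern, with the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position + 1})")
        self.position = position


@dataclass(frozen=True)
class PatternElement:
    kind: str  # literal | set | negated | wildcard
    residues: frozenset[str] = frozenset()
    min_repeat: int = 1
    max_repeat: int = 1

    def allows(self, ch: str) -> bool:
        if self.kind == "wildcard":
            return True
        if self.kind == "negated":
            return ch not in self.residues
        return ch in self.residues

    def render(self) -> str:
        if self.kind == "literal":
            return next(iter(self.residues))
        if self.kind == "set":
            return "[" + "".join(sorted(self.residues)) + "]"
        if self.kind == "negated":
            return "{" + "".join(sorted(self.residues)) + "}"
        if self.min_repeat == self.max_repeat:
            return "x" if self.min_repeat == 1 else f"x({self.min_repeat})"
        return f"x({self.min_repeat},{self.max_repeat})"


@dataclass
class PrositePattern:
    elements: list[PatternElement]
    source: str

    @property
    def min_length(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def is_fixed_length(self) -> bool:
        return all(e.min_repeat == e.max_repeat for e in self.elements)

    def render(self) -> str:
        """Normalized pattern text (round-trips through the parser)."""
        return "-".join(e.render() for e in self.elements)

    def matches(self, fragment: str) -> bool:
        """Whether the whole fragment satisfies the pattern."""
        return _match_here(fragment.upper(), 0, self.elements, full=True) is not None


@dataclass
class PatternMatch:
    sequence_id: str
    start: int  # 1-based
    matched: str
    pattern: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched) - 1


_TOKEN = re.compile(
    r"(?P<set>\[[A-Za-z]+\])|(?P<neg>\{[A-Za-z]+\})|(?P<wild>[xX](\((?P<n>\d+)(,(?P<m>\d+))?\))?)"
    r"|(?P<lit>[A-WYZa-wyz])"
)


def parse_pattern(text: str) -> PrositePattern:
    """Parse a PROSITE pattern string into its element list."""
    if not text or not text.strip():
        raise PatternSyntaxError("empty pattern", 0)
    src = text.strip().rstrip(".")
    elements: list[PatternElement] = []
    pos = 0
    expect_sep = False
    while pos < len(src):
        if expect_sep:
            if src[pos] != "-":
                raise PatternSyntaxError(f"expected '-' but found {src[pos]!r}", pos)
            pos += 1
        m = _TOKEN.match(src, pos)
        if m is None or m.start() != pos:
            raise PatternSyntaxError(f"unrecognized pattern syntax {src[pos]!r}", pos)
        if m.lastgroup is None:
            raise PatternSyntaxError("unrecognized pattern syntax", pos)
        if m.group("set"):
            residues = frozenset(m.group("set")[1:-1].upper())
            _check_residues(residues, pos)
            elements.append(PatternElement("set", residues))
        elif m.group("neg"):
            residues = frozenset(m.group("neg")[1:-1].upper())
            _check_residues(residues, pos)
            elements.append(PatternElement("negated", residues))
        elif m.group("wild") is not None:
            lo = int(m.group("n")) if m.group("n") else 1
            hi = int(m.group("m")) if m.group("m") else lo
            if hi < lo or lo < 1:
                raise PatternSyntaxError(f"invalid repeat range ({lo},{hi})", pos)
            elements.append(PatternElement("wildcard", min_repeat=lo, max_repeat=hi))
        else:
            ch = m.group("lit").upper()
            _check_residues({ch}, pos)
            elements.append(PatternElement("literal", frozenset(ch)))
        pos = m.end()
        expect_sep = True
    if not elements:
        raise PatternSyntaxError("empty pattern", 0)
    return PrositePattern(elements, src)


def _check_residues(residues, pos: int) -> None:
    bad = set(residues) - set(AMINO_ACIDS)
    if bad:
        raise PatternSyntaxError(f"not amino-acid codes: {sorted(bad)}", pos)


def _match_here(seq: str, start: int, elements, full: bool = False) -> int | None:
    """Length of a match of ``elements`` starting at ``start``, else None.

    Repeats are greedy with backtracking; ``full`` additionally requires
    the match to consume the whole string.
    """
    if not elements:
        if full and start != len(seq):
            return None
        return 0
    head, rest = elements[0], elements[1:]
    if head.kind == "wildcard":
        hi = min(head.max_repeat, len(seq) - start)
        for take in range(hi, head.min_repeat - 1, -1):
            sub = _match_here(seq, start + take, rest, full)
            if sub is not None:
                return take + sub
        return None
    if start >= len(seq) or not head.allows(seq[start]):
        return None
    sub = _match_here(seq, start + 1, rest, full)
    return None if sub is None else 1 + sub


def scan(
    seq: DomainSequence | str,
    pattern: PrositePattern | str,
    overlap: bool = True,
) -> list[PatternMatch]:
    """All matches of a pattern in a sequence, 1-based ascending starts.

    With ``overlap=False`` only leftmost non-overlapping matches are kept.
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    if isinstance(seq, str):
        sid, residues = "query", seq.upper()
    else:
        sid, residues = seq.id, seq.residues
    matches: list[PatternMatch] = []
    next_allowed = 0
    for start in range(len(residues) - pattern.min_length + 1):
        if not overlap and start < next_allowed:
            continue
        length = _match_here(residues, start, pattern.elements)
        if length is not None:
            matches.append(
                PatternMatch(sid, start + 1, residues[start : start + length], pattern.render())
            )
            next_allowed = start + length
    return matches


def downstream_window(
    protein: DomainSequence, domain_end: int, window: int = DOWNSTREAM_WINDOW
) -> tuple[DomainSequence | None, int]:
    """The region immediately downstream of the domain.

    Returns (subsequence, length); the subsequence is None (flagged) when
    the protein stops exactly at the domain end. The region runs from
    ``domain_end + 1`` to ``min(domain_end + window, len(protein))`` in
    1-based coordinates, so proteins that stop shortly after the domain
    yield a correspondingly short window.
    """
    if not (1 <= domain_end <= len(protein)):
        raise ValueError(f"domain_end {domain_end} outside protein of length {len(protein)}")
    if domain_end == len(protein):
        return None, 0
    sub = protein.residues[domain_end : domain_end + window]
    out = DomainSequence(
        id=f"{protein.id}_downstream",
        residues=sub,
        taxon=protein.taxon,
        domain_class=protein.domain_class,
    )
    return out, len(sub)


def expected_hits(
    pattern: PrositePattern | str,
    seq_length: int,
    residue_freqs: Sequence[float] | None = None,
) -> float:
    """Analytic expected match count on an i.i.d. random sequence.

    The per-window match probability is the product over pattern
    positions of the allowed-set probability (wildcards contribute 1,
    variable-length repeats use their minimum span); expected hits are
    probability x (seq_length - min_length + 1).
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    freqs = (
        np.full(20, 0.05) if residue_freqs is None else np.asarray(residue_freqs, dtype=float)
    )
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError("residue frequencies must sum to 1")
    lookup = dict(zip(AMINO_ACIDS, freqs))
    prob = 1.0
    for el in pattern.elements:
        if el.kind == "wildcard":
            continue
        p = sum(lookup[a] for a in el.residues)
        prob *= (1.0 - p) if el.kind == "negated" else p
    n_windows = max(seq_length - pattern.min_length + 1, 0)
    return prob * n_windows


def sample_pattern_instance(pattern: PrositePattern | str, rng: np.random.Generator) -> str:
    """One string drawn uniformly from the pattern's language."""
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    out = []
    for el in pattern.elements:
        if el.kind == "wildcard":
            n = int(rng.integers(el.min_repeat, el.max_repeat + 1))
            out.append("".join(rng.choice(list(AMINO_ACIDS), size=n)))
        elif el.kind == "negated":
            allowed = sorted(set(AMINO_ACIDS) - el.residues)
            out.append(str(rng.choice(allowed)))
        else:
            out.append(str(rng.choice(sorted(el.residues))))
    return "".join(out)
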