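"""Protein domain sequences and their on-disk formats.

The package works with short protein domain sequences (the ~40-residue
DNA-binding core of the fungal mating-type alpha1 domain and of the
MATA_HMG / SOX / HMGB classes of the HMG-box superfamily), read either
from FASTA or from a simple tabular (id, class, sequence) format.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues treated as missing data (unknown amino acid)
MISSING_RESIDUES = frozenset("X")
GAP = "-"


class DomainClass(enum.Enum):
    """Domain-family label for a sequence.

    ALPHA1_A is the Pleosporales alpha1 clade (core two residues shorter
    than MATA_HMG), ALPHA1_B the alpha1 clade of the remaining
    Pezizomycotina (four residues shorter).
    """

    ALPHA1_A = "alpha1-a"
    ALPHA1_B = "alpha1-b"
    MATA_HMG = "MATA_HMG"
    SOX = "SOX"
    HMGB = "HMGB"
    UNKNOWN = "unknown"

    @classmethod
    def from_label(cls, label: str) -> "DomainClass":
        label = label.strip()
        for member in cls:
            if member.value.lower() == label.lower() or member.name.lower() == label.lower():
                return member
        return cls.UNKNOWN


class UnknownResidueError(ValueError):
    """A residue has no entry in the scoring table in use."""


@dataclass(frozen=True)
class DomainSequence:
    """One protein (or domain core) with identifier, taxon and class label.

    ``residues`` is an upper-case string over the 20 amino-acid letters,
    optionally containing ``X`` for unknown residues; gaps are not allowed
    (aligned rows live in :class:`~mat_alpha_trace.profiles.Alignment`).
    """

    id: str
    residues: str
    taxon: str = ""
    domain_class: DomainClass = DomainClass.UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: residues must be non-empty")
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if GAP in residues:
            raise ValueError(f"{self.id}: residues must not contain gap characters")
        bad = set(residues) - set(AMINO_ACIDS) - MISSING_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


def check_unique_ids(seqs: Sequence[DomainSequence]) -> None:
    seen: set[str] = set()
    for s in seqs:
        if s.id in seen:
            raise ValueError(f"duplicate sequence id: {s.id}")
        seen.add(s.id)


def read_fasta(path: str | Path, domain_class: DomainClass = DomainClass.UNKNOWN) -> list[DomainSequence]:
    """Read (possibly wrapped) FASTA into domain sequences.

    The description after the identifier, if any, is kept as the taxon label.
    """
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = rec.description[len(rec.id):].strip()
        seqs.append(DomainSequence(rec.id, str(rec.seq), taxon=taxon, domain_class=domain_class))
    check_unique_ids(seqs)
    return seqs


def write_fasta(seqs: Iterable[DomainSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.taxon or "")
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_table(path: str | Path) -> list[DomainSequence]:
    """Read a tabular dataset with columns id, class, sequence (CSV or TSV)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("id", "class", "sequence"):
        if required not in cols:
            raise ValueError(f"{path}: missing column '{required}'")
    seqs = [
        DomainSequence(
            str(row[cols["id"]]),
            str(row[cols["sequence"]]),
            domain_class=DomainClass.from_label(str(row[cols["class"]])),
        )
        for _, row in df.iterrows()
    ]
    check_unique_ids(seqs)
    return seqs


def write_table(seqs: Iterable[DomainSequence], path: str | Path) -> None:
    seqs = list(seqs)
    df = pd.DataFrame(
        {
            "id": [s.id for s in seqs],
            "class": [s.domain_class.value for s in seqs],
            "sequence": [s.residues for s in seqs],
        }
    )
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)
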