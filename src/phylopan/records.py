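"""Protein sequence records and FASTA I/O.

A :class:`ProteinRecord` is the unit every clustering stage operates on: an
amino-acid sequence tagged with the genome (or environmental sample) it came
from. FASTA reading and writing is delegated to Biopython.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein.

    Parameters
    ----------
    id:
        Unique record identifier (conventionally ``<genome>|<gene>``).
    genome:
        Label of the genome or sample of origin.
    sequence:
        Amino-acid sequence over the 20 standard residues plus ``X``.
    """

    id: str
    genome: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if not _VALID.match(self.sequence):
            bad = sorted(set(self.sequence) - set(AMINO_ACIDS + "X"))
            raise ValueError(f"record {self.id!r} contains invalid symbols {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, genome: str | None = None) -> list[ProteinRecord]:
    """Read a protein multi-FASTA; the genome label defaults to the file stem."""
    path = Path(path)
    label = genome if genome is not None else path.stem
    records = [
        ProteinRecord(id=rec.id, genome=label, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def check_unique_ids(records: Sequence[ProteinRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
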