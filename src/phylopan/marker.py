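"""Pairwise marker-gene distances under WAG, and amplicon extraction.

For two aligned protein sequences the evolutionary distance is the branch
length t maximizing the likelihood of one sequence having evolved from the
other under the reversible model:

    ln L(t) = sum_sites ln( pi_x * P_xy(t) )

Columns with a gap (or ``X``) in either sequence are dropped pair-by-pair
(pairwise deletion). The 1-D likelihood is maximized by bounded Brent search
on t in [1e-6, 20]. Simple p- and Poisson-corrected distances are provided
as fast cross-checks. An "amplicon" is a fixed column window of the
alignment, emulating the marker-gene fragment a PCR assay would recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.optimize import minimize_scalar

from .distance import DistanceMatrix
from .wag import SubstitutionModel, wag_model

T_MIN = 1e-6
T_MAX = 20.0


class UndefinedDistanceError(ValueError):
    """Raised when a pairwise distance is not defined for the inputs."""


@dataclass
class MarkerAlignment:
    """A gap-aware protein alignment with unique labels."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("alignment labels must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def get(self, label: str) -> str:
        return self.sequences[self.labels.index(label)]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MarkerAlignment":
        labels, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(labels=labels, sequences=seqs)

    def to_fasta(self, path: str | Path) -> None:
        SeqIO.write(
            [SeqRecord(Seq(s), id=l, description="") for l, s in zip(self.labels, self.sequences)],
            str(path),
            "fasta",
        )


def _pair_counts(a: str, b: str, model: SubstitutionModel) -> np.ndarray:
    """20x20 site-pattern counts over shared-residue columns."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    idx = {c: i for i, c in enumerate(model.alphabet)}
    C = np.zeros((20, 20))
    for ca, cb in zip(a, b):
        ia, ib = idx.get(ca), idx.get(cb)
        if ia is not None and ib is not None:
            C[ia, ib] += 1
    return C


def pairwise_ml_distance(
    a: str, b: str, model: SubstitutionModel | None = None
) -> float:
    """Maximum-likelihood WAG distance between two aligned sequences."""
    model = model or wag_model()
    C = _pair_counts(a, b, model)
    if C.sum() == 0:
        raise UndefinedDistanceError("no shared residue columns")
    log_pi = np.log(model.frequencies)
    pi_term = float(np.sum(C.sum(axis=1) * log_pi))

    def negll(t: float) -> float:
        P = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            lp = np.log(P)
        lp[C == 0] = 0.0  # avoid -inf * 0
        return -(pi_term + float(np.sum(C * lp)))

    res = minimize_scalar(
        negll, bounds=(T_MIN, T_MAX), method="bounded", options={"xatol": 1e-8}
    )
    return float(res.x)


def corrected_distance(a: str, b: str, kind: str = "p") -> float:
    """p-distance or Poisson-corrected distance over shared-residue columns."""
    model = wag_model()
    C = _pair_counts(a, b, model)
    total = C.sum()
    if total == 0:
        raise UndefinedDistanceError("no shared residue columns")
    p = float((total - np.trace(C)) / total)
    if kind == "p":
        return p
    if kind == "poisson":
        if p >= 1.0:
            raise UndefinedDistanceError("p-distance of 1 cannot be corrected")
        return -np.log(1.0 - p)
    raise ValueError(f"unknown correction kind {kind!r}")


def marker_distance_matrix(
    msa: MarkerAlignment, model: SubstitutionModel | None = None
) -> DistanceMatrix:
    """All pairwise ML distances of an alignment."""
    if len(msa) < 3:
        raise ValueError("need at least 3 sequences")
    model = model or wag_model()
    n = len(msa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_ml_distance(msa.sequences[i], msa.sequences[j], model)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=list(msa.labels), values=values)


def extract_amplicon(
    msa: MarkerAlignment, window: tuple[int, int] = (300, 440)
) -> MarkerAlignment:
    """Column slice [start, stop) of the alignment; labels preserved."""
    start, stop = window
    if not (0 <= start < stop <= msa.n_columns):
        raise ValueError(
            f"window [{start}, {stop}) outside alignment of {msa.n_columns} columns"
        )
    return MarkerAlignment(
        labels=list(msa.labels),
        sequences=[s[start:stop] for s in msa.sequences],
    )
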