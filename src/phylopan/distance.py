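"""Labeled distance matrices and the gene-content distance.

The gene-content distance between genomes i and j is

    D_ij = -ln( S_ij / sqrt(N_i * N_j) )

with S_ij the number of shared gene clusters and N_i, N_j the genomes'
cluster counts. Identical repertoires give 0; disjoint repertoires would be
infinite, so S_ij = 0 is capped with a pseudo-count of 0.5 and the pair is
flagged. D is not guaranteed metric; it is consumed as-is by neighbor
joining and by the Mantel congruence test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cluster import PresenceAbsenceMatrix


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=0.0):
            raise ValueError("distance matrix must be exactly symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def condensed(self) -> np.ndarray:
        """Strict lower triangle, row-major (the vector Mantel correlates)."""
        return self.values[np.tril_indices(len(self.labels), -1)]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join([""] + self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write("\t".join([lab] + [f"{v:.4f}" for v in row]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            labels = header[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(v) for v in parts[1:]])
        values = np.array(rows)
        # symmetrize away printed rounding asymmetries, if any
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        return cls(labels=labels, values=values)


def gene_content_distance(sij: int, ni: int, nj: int) -> tuple[float, bool]:
    """D_ij = -ln(S_ij / sqrt(N_i N_j)); returns ``(distance, capped)``.

    ``capped`` is True when S_ij = 0 and the 0.5 pseudo-count was applied.
    """
    if ni < 1 or nj < 1:
        raise ValueError("gene counts must be >= 1")
    if sij < 0 or sij > min(ni, nj):
        raise ValueError(f"shared count {sij} outside [0, min({ni}, {nj})]")
    if sij == 0:
        return -math.log(0.5 / math.sqrt(ni * nj)), True
    return -math.log(sij / math.sqrt(ni * nj)), False


def distance_matrix_from_pa(pa: PresenceAbsenceMatrix) -> DistanceMatrix:
    """All pairwise gene-content distances from an incidence matrix."""
    if len(pa.genomes) < 3:
        raise ValueError("need at least 3 genomes for a distance matrix")
    n_genes = pa.gene_counts()
    if np.any(n_genes == 0):
        empty = [g for g, c in zip(pa.genomes, n_genes) if c == 0]
        raise ValueError(f"genomes with empty repertoires: {empty}")
    shared = pa.shared_matrix()
    n = len(pa.genomes)
    values = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            d, capped = gene_content_distance(
                int(shared[i, j]), int(n_genes[i]), int(n_genes[j])
            )
            values[i, j] = values[j, i] = d
            if capped:
                flagged.append((pa.genomes[i], pa.genomes[j]))
    return DistanceMatrix(labels=list(pa.genomes), values=values, flagged_pairs=flagged)


def subset_matrix(d: DistanceMatrix, keep: Sequence[str]) -> DistanceMatrix:
    """Restrict to the given labels, preserving the order of ``keep``."""
    unknown = set(keep) - set(d.labels)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    if len(keep) < 3:
        raise ValueError("a distance matrix needs at least 3 labels")
    return d.reorder(list(keep))
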