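"""Congruence of distance matrices and amplicon-threshold calibration.

The Mantel test asks whether two distance matrices over the same taxa are
correlated: r is the Pearson correlation of their strict lower triangles,
and significance comes from permuting one matrix's labels. Here it links
gene-content distances to marker-gene distances — a high r means the marker
phylogeny is a usable proxy for gene content.

Calibration asks at which amplicon identity threshold co-clustered taxa
have nearly identical full-length marker distances: for each threshold the
amplicons are greedily clustered and the standard deviation of full-length
distances pooled over multi-member clusters is recorded. The chosen
threshold is the smallest one whose spread drops below a tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cluster import greedy_cluster
from .distance import DistanceMatrix, subset_matrix  # noqa: F401  (re-export)
from .marker import MarkerAlignment
from .records import ProteinRecord


@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int
    tail: str


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
    tail: str = "upper",
) -> MantelResult:
    """Mantel correlation between two labeled distance matrices.

    ``d2`` is aligned to ``d1``'s label order first. The permutation p-value
    is ``(#{r_perm >= r_obs} + 1) / (permutations + 1)`` for the upper tail
    (absolute values for ``two-sided``).
    """
    if set(d1.labels) != set(d2.labels):
        raise ValueError("matrices must share an identical label set")
    n = len(d1.labels)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 taxa")
    if tail not in ("upper", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    d2 = d2.reorder(d1.labels)
    tril = np.tril_indices(n, -1)
    v1 = d1.values[tril]
    m2 = d2.values

    def corr(vec: np.ndarray) -> float:
        return float(np.corrcoef(v1, vec)[0, 1])

    r_obs = corr(m2[tril])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r_perm = corr(m2[np.ix_(perm, perm)][tril])
        if tail == "upper":
            hits += r_perm >= r_obs
        else:
            hits += abs(r_perm) >= abs(r_obs)
    p = (hits + 1) / (permutations + 1)
    return MantelResult(r=r_obs, p=p, permutations=permutations, tail=tail)


@dataclass
class CalibrationCurve:
    """Within-cluster spread of full-length distances per identity threshold."""

    thresholds: list[float]
    stdv: list[float | None]  # None where fewer than 2 pairs contribute
    n_pairs: list[int]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tstdv\tn_pairs\n")
            for t, s, n in zip(self.thresholds, self.stdv, self.n_pairs):
                s_txt = "" if s is None else f"{s:.6f}"
                fh.write(f"{t:.4f}\t{s_txt}\t{n}\n")


def _pooled_pairs(
    full_dist: DistanceMatrix, amplicons: MarkerAlignment, threshold: float
) -> list[float]:
    records = [
        ProteinRecord(id=lab, genome=lab, sequence=seq.replace("-", ""))
        for lab, seq in zip(amplicons.labels, amplicons.sequences)
    ]
    clusters = greedy_cluster(records, threshold=threshold)
    pooled: list[float] = []
    for cl in clusters.clusters:
        labs = [m.id for m in cl.members]
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                pooled.append(full_dist.get(labs[i], labs[j]))
    return pooled


def calibration_curve(
    full_dist: DistanceMatrix,
    amplicons: MarkerAlignment,
    thresholds: list[float] | None = None,
) -> CalibrationCurve:
    """Spread of full-length distances within amplicon clusters, per threshold.

    Default threshold grid: 0.70 to 1.00 in steps of 0.01.
    """
    if len(amplicons) == 0:
        raise ValueError("no amplicon sequences")
    missing = set(amplicons.labels) - set(full_dist.labels)
    if missing:
        raise ValueError(f"amplicon labels missing from distance matrix: {sorted(missing)}")
    if thresholds is None:
        thresholds = [round(0.70 + 0.01 * k, 2) for k in range(31)]
    if sorted(thresholds) != list(thresholds) or len(set(thresholds)) != len(thresholds):
        raise ValueError("thresholds must be strictly increasing")
    stdv: list[float | None] = []
    n_pairs: list[int] = []
    for g in thresholds:
        pooled = _pooled_pairs(full_dist, amplicons, g)
        n_pairs.append(len(pooled))
        if len(pooled) < 2:
            stdv.append(None)
        else:
            stdv.append(float(np.std(pooled, ddof=1)))
    return CalibrationCurve(thresholds=list(thresholds), stdv=stdv, n_pairs=n_pairs)


def select_threshold(
    curve: CalibrationCurve, epsilon: float = 0.05
) -> tuple[float, bool]:
    """Smallest threshold whose spread is at most epsilon.

    Returns ``(threshold, satisfied)``; when no threshold qualifies the one
    with minimal defined spread is returned with ``satisfied=False``.
    """
    if not curve.thresholds:
        raise ValueError("empty calibration curve")
    defined = [(t, s) for t, s in zip(curve.thresholds, curve.stdv) if s is not None]
    if not defined:
        raise ValueError("spread undefined at every threshold")
    for t, s in defined:
        if s <= epsilon:
            return t, True
    best = min(defined, key=lambda ts: (ts[1], ts[0]))
    return best[0], False
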