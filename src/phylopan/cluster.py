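"""Greedy centroid clustering of proteins and the presence-absence matrix.

Proteins from all genomes are pooled and clustered at a fractional
amino-acid identity threshold (default 0.5): records are processed in
decreasing length order (ties by id), each joining the first existing
centroid it matches at or above the threshold, otherwise founding a new
cluster. This is the UCLUST-style greedy rule; the resulting clusters stand
in for ortholog families. The genome x cluster incidence matrix derived from
them is the input to gene-content distances, Venn-style shared counts and
the core/pan partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import identity_upper_bound, pairwise_identity
from .records import ProteinRecord, check_unique_ids

DEFAULT_IDENTITY_THRESHOLD = 0.5


@dataclass
class GeneCluster:
    centroid: ProteinRecord
    members: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            self.members = [self.centroid]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def genomes(self) -> set[str]:
        return {m.genome for m in self.members}


@dataclass
class GeneClusterSet:
    clusters: list[GeneCluster]
    threshold: float

    def __len__(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        """Map record id -> cluster index."""
        out: dict[str, int] = {}
        for i, cl in enumerate(self.clusters):
            for m in cl.members:
                out[m.id] = i
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cluster_id\tcentroid_id\tmember_id\tgenome\n")
            for i, cl in enumerate(self.clusters):
                for m in cl.members:
                    fh.write(f"c{i:05d}\t{cl.centroid.id}\t{m.id}\t{m.genome}\n")


def greedy_cluster(
    records: Sequence[ProteinRecord],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    seeds: Sequence[ProteinRecord] = (),
    prescreen: bool = True,
) -> GeneClusterSet:
    """Cluster records at a fractional identity threshold.

    Parameters
    ----------
    records:
        Proteins to cluster; processed in decreasing length order, ties
        broken by id (lexicographic).
    threshold:
        Minimum identity to the centroid for membership, in (0, 1].
    seeds:
        Records installed as the first centroids, in the given order and
        before any length sorting; used to anchor OTU clusters on reference
        sequences.
    prescreen:
        Apply the edit-distance identity upper bound before the affine
        alignment. The bound is conservative, so the clustering result is
        identical with or without it.
    """
    if not records and not seeds:
        raise ValueError("no records to cluster")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    check_unique_ids(list(seeds) + list(records))

    clusters: list[GeneCluster] = [GeneCluster(centroid=s) for s in seeds]
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    for rec in ordered:
        home = None
        for cl in clusters:
            if prescreen and identity_upper_bound(rec.sequence, cl.centroid.sequence) < threshold:
                continue
            if pairwise_identity(rec.sequence, cl.centroid.sequence) >= threshold:
                home = cl
                break
        if home is None:
            clusters.append(GeneCluster(centroid=rec))
        else:
            home.members.append(rec)
    return GeneClusterSet(clusters=clusters, threshold=threshold)


@dataclass
class PresenceAbsenceMatrix:
    """Genome x gene-cluster incidence (multi-copy genes collapse to one)."""

    genomes: list[str]
    cluster_ids: list[str]
    incidence: np.ndarray  # bool, shape (n_genomes, n_clusters)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)
        if self.incidence.shape != (len(self.genomes), len(self.cluster_ids)):
            raise ValueError("incidence shape does not match labels")

    def row(self, genome: str) -> np.ndarray:
        return self.incidence[self.genomes.index(genome)]

    def gene_counts(self) -> np.ndarray:
        """Per-genome cluster counts (the Ni of the distance formula)."""
        return self.incidence.sum(axis=1)

    def shared_matrix(self) -> np.ndarray:
        """Pairwise shared-cluster counts Sij = rows_i . rows_j."""
        m = self.incidence.astype(np.int64)
        return m @ m.T

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(["genome"] + self.cluster_ids) + "\n")
            for g, row in zip(self.genomes, self.incidence):
                fh.write("\t".join([g] + [str(int(v)) for v in row]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceAbsenceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cluster_ids = header[1:]
            genomes, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                genomes.append(parts[0])
                rows.append([bool(int(v)) for v in parts[1:]])
        return cls(genomes=genomes, cluster_ids=cluster_ids, incidence=np.array(rows))

    @classmethod
    def from_membership(
        cls, membership: Mapping[str, Iterable[str]]
    ) -> "PresenceAbsenceMatrix":
        """Build from a genome -> family-id mapping (simulation truth)."""
        genomes = sorted(membership)
        families = sorted({f for fams in membership.values() for f in fams})
        idx = {f: j for j, f in enumerate(families)}
        inc = np.zeros((len(genomes), len(families)), dtype=bool)
        for i, g in enumerate(genomes):
            for f in membership[g]:
                inc[i, idx[f]] = True
        return cls(genomes=genomes, cluster_ids=families, incidence=inc)


def build_presence_absence(clusters: GeneClusterSet) -> PresenceAbsenceMatrix:
    """Incidence of genomes in gene clusters; one column per cluster."""
    genomes = sorted({m.genome for cl in clusters.clusters for m in cl.members})
    gidx = {g: i for i, g in enumerate(genomes)}
    inc = np.zeros((len(genomes), len(clusters.clusters)), dtype=bool)
    ids = []
    for j, cl in enumerate(clusters.clusters):
        ids.append(f"c{j:05d}")
        for m in cl.members:
            inc[gidx[m.genome], j] = True
    return PresenceAbsenceMatrix(genomes=genomes, cluster_ids=ids, incidence=inc)


def shared_counts(
    pa: PresenceAbsenceMatrix, subset: Sequence[str] | None = None
) -> dict:
    """Venn-style summary for a genome subset.

    Returns the number of clusters present in all chosen genomes, in at
    least two, in exactly one (unique), and each pairwise shared count.
    Clusters absent from every chosen genome are ignored.
    """
    genomes = list(pa.genomes) if subset is None else list(subset)
    unknown = set(genomes) - set(pa.genomes)
    if unknown:
        raise ValueError(f"unknown genome labels: {sorted(unknown)}")
    rows = np.array([pa.row(g) for g in genomes])
    present = rows.sum(axis=0)
    counts = {
        "all": int(np.sum(present == len(genomes))),
        "at_least_two": int(np.sum(present >= 2)),
        "unique": int(np.sum(present == 1)),
        "pairwise": {},
    }
    for i, gi in enumerate(genomes):
        for j in range(i + 1, len(genomes)):
            counts["pairwise"][(gi, genomes[j])] = int(np.sum(rows[i] & rows[j]))
    return counts


def core_pan_partition(pa: PresenceAbsenceMatrix) -> tuple[list[str], list[str]]:
    """Split clusters into core (present in every genome) and pan (the rest)."""
    if len(pa.genomes) < 2:
        raise ValueError("core/pan partition needs at least two genomes")
    in_all = pa.incidence.all(axis=0)
    core = [c for c, flag in zip(pa.cluster_ids, in_all) if flag]
    pan = [c for c, flag in zip(pa.cluster_ids, in_all) if not flag]
    return core, pan
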