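"""Amplicon OTU analysis: cluster, de-singleton, assign, rarefy.

Environmental marker-gene amplicons (amino-acid reads, one FASTA per
sample) are pooled with reference sequences and clustered greedily at 97%
identity; the references are seeded as the first centroids so
reference-anchored OTUs keep stable identifiers. Single-member clusters are
discarded, reads are assigned to their best centroid, and the resulting
sample x OTU table is rarefied without replacement to the smallest sample
depth (vegan ``rrarefy`` semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import identity_upper_bound, pairwise_identity
from .cluster import GeneCluster, GeneClusterSet, greedy_cluster
from .records import ProteinRecord

DEFAULT_OTU_IDENTITY = 0.97


@dataclass
class OTUTable:
    """Sample x OTU counts; rows sum to ``depth`` once rarefied."""

    counts: pd.DataFrame  # index: samples, columns: OTU ids, int
    reference_otus: list[str] = field(default_factory=list)
    rarefied: bool = False
    depth: int | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.rarefied:
            sums = self.counts.sum(axis=1)
            if self.depth is None or not (sums == self.depth).all():
                raise ValueError("rarefied table rows must all sum to depth")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otus(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OTUTable":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(counts=df.astype(int))


def _dereplicate(reads: Sequence[ProteinRecord]) -> dict[str, list[ProteinRecord]]:
    by_seq: dict[str, list[ProteinRecord]] = {}
    for r in reads:
        by_seq.setdefault(r.sequence, []).append(r)
    for members in by_seq.values():
        members.sort(key=lambda r: r.id)
    return by_seq


def otu_cluster(
    reads: Sequence[ProteinRecord],
    references: Sequence[ProteinRecord] = (),
    threshold: float = DEFAULT_OTU_IDENTITY,
) -> GeneClusterSet:
    """Greedy clustering of pooled reads with reference-seeded centroids.

    Exact duplicate reads are collapsed before alignment and re-expanded in
    the result, so the output partition covers every input read.
    """
    if not reads and not references:
        raise ValueError("no sequences to cluster")
    by_seq = _dereplicate(reads)
    reps = [members[0] for members in by_seq.values()]
    rep_clusters = greedy_cluster(reps, threshold=threshold, seeds=list(references))
    clusters = []
    for cl in rep_clusters.clusters:
        members: list[ProteinRecord] = []
        for m in cl.members:
            members.extend(by_seq.get(m.sequence, []) if m.id not in _ids(references) else [m])
        # a reference seed whose sequence equals a read's still anchors both
        if cl.centroid.id in _ids(references) and cl.centroid not in members:
            members = [cl.centroid] + members
        clusters.append(GeneCluster(centroid=cl.centroid, members=members))
    return GeneClusterSet(clusters=clusters, threshold=threshold)


def _ids(records: Sequence[ProteinRecord]) -> set[str]:
    return {r.id for r in records}


def discard_singletons(
    clusters: GeneClusterSet,
    references: Sequence[ProteinRecord] = (),
    keep_references: bool = False,
) -> GeneClusterSet:
    """Drop single-member clusters.

    A reference seed with no reads is a size-1 cluster and is dropped
    unless ``keep_references`` is set.
    """
    ref_ids = _ids(references)
    kept = []
    for cl in clusters.clusters:
        if cl.size >= 2:
            kept.append(cl)
        elif keep_references and cl.centroid.id in ref_ids:
            kept.append(cl)
    return GeneClusterSet(clusters=kept, threshold=clusters.threshold)


def assign_reads(
    reads: Sequence[ProteinRecord],
    centroids: Sequence[ProteinRecord],
    threshold: float = DEFAULT_OTU_IDENTITY,
    reference_ids: Sequence[str] = (),
) -> tuple[OTUTable, dict[str, int]]:
    """Assign each read to its best-identity centroid at or above threshold.

    Ties go to the earliest centroid in creation order. Returns the
    sample x OTU count table and the per-sample count of unassigned reads.
    Read sample labels are taken from ``ProteinRecord.genome``.
    """
    if not centroids:
        raise ValueError("no centroids to assign against")
    samples = sorted({r.genome for r in reads})
    otu_ids = [c.id for c in centroids]
    counts = pd.DataFrame(0, index=samples, columns=otu_ids, dtype=int)
    unassigned = {s: 0 for s in samples}

    cache: dict[str, int | None] = {}
    for read in reads:
        if read.sequence in cache:
            best = cache[read.sequence]
        else:
            best, best_ident = None, threshold
            for k, cen in enumerate(centroids):
                if identity_upper_bound(read.sequence, cen.sequence) < best_ident:
                    continue
                ident = pairwise_identity(read.sequence, cen.sequence)
                if ident > best_ident or (best is None and ident >= best_ident):
                    best, best_ident = k, ident
            cache[read.sequence] = best
        if best is None:
            unassigned[read.genome] += 1
        else:
            counts.loc[read.genome, otu_ids[best]] += 1
    table = OTUTable(counts=counts, reference_otus=[i for i in otu_ids if i in set(reference_ids)])
    return table, unassigned


def rarefy(table: OTUTable, seed: int = 0) -> OTUTable:
    """Subsample every sample without replacement to the minimum row sum."""
    sums = table.counts.sum(axis=1)
    if (sums == 0).any():
        empty = list(sums.index[sums == 0])
        raise ValueError(f"samples with zero reads cannot be rarefied: {empty}")
    depth = int(sums.min())
    rng = np.random.default_rng(seed)
    rows = []
    for _, row in table.counts.iterrows():
        rows.append(rng.multivariate_hypergeometric(row.values.astype(np.int64), depth))
    counts = pd.DataFrame(rows, index=table.counts.index, columns=table.counts.columns)
    return OTUTable(
        counts=counts,
        reference_otus=list(table.reference_otus),
        rarefied=True,
        depth=depth,
    )


def dominant_otus(table: OTUTable, top_k: int = 1) -> dict[str, list[str]]:
    """Per sample, the k highest-count OTUs (ties by OTU label order)."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    out: dict[str, list[str]] = {}
    for sample, row in table.counts.iterrows():
        nonzero = [(otu, c) for otu, c in row.items() if c > 0]
        nonzero.sort(key=lambda oc: (-oc[1], oc[0]))
        out[sample] = [otu for otu, _ in nonzero[:top_k]]
    return out


def annotation_tsv(table: OTUTable, path: str | Path) -> None:
    """Long-format (otu, sample, count) table for tree decoration."""
    with open(path, "w") as fh:
        fh.write("otu_id\tsample\tcount\n")
        for sample, row in table.counts.iterrows():
            for otu, c in row.items():
                if c > 0:
                    fh.write(f"{otu}\t{sample}\t{int(c)}\n")
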