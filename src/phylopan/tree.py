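"""Neighbor-joining trees, bipartitions, Robinson-Foulds, and bootstrap.

Trees are held as :class:`dendropy.Tree` objects interpreted as unrooted
(the NJ construction leaves a degree-3 central node). Newick output uses a
canonical child ordering (by smallest descendant leaf label) so that
write -> read -> write is idempotent. Bipartition supports estimated by
resampling gene-cluster columns are attached to internal edges as node
attributes and written as internal node labels.
"""

from __future__ import annotations

import io
import math
from typing import Iterable

import dendropy
import numpy as np

from .cluster import PresenceAbsenceMatrix
from .distance import DistanceMatrix, distance_matrix_from_pa


# ---------------------------------------------------------------------------
# construction and I/O helpers


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")


def _min_leaf(node: dendropy.Node) -> str:
    return min(lf.taxon.label for lf in node.leaf_iter())


def write_newick(tree: dendropy.Tree, include_support: bool = False) -> str:
    """Canonical Newick string (children ordered by smallest leaf label)."""

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            core = node.taxon.label
        else:
            kids = sorted(node.child_nodes(), key=_min_leaf)
            core = "(" + ",".join(render(k) for k in kids) + ")"
            support = getattr(node, "support", None)
            if include_support and support is not None:
                core += f"{support:.3f}"
        length = node.edge.length
        if node.parent_node is not None and length is not None:
            core += f":{length:.10g}"
        return core

    return render(tree.seed_node) + ";"


def tree_from_newick_file(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou-Nei neighbor joining.

    At each step the pair minimizing the Q-criterion is joined; exact ties
    are broken by the lexicographically smallest (sorted) pair of node keys,
    where a node's key is its smallest descendant leaf label. Negative
    branch lengths are clamped to zero; the clamped deficit is accumulated
    on the returned tree as ``tree.clamped_negative_total``.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace(d.labels)
    nodes = []
    for lab in d.labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
    keys = list(d.labels)
    D = d.values.copy()
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0.0:
            clamped += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        candidates = [
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i in range(m)
            for j in range(i + 1, m)
            if Q[i, j] <= qmin + tol
        ]
        _, i, j = min(candidates)
        bi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = D[i, j] - bi
        parent = dendropy.Node()
        nodes[i].edge.length = clamp(bi)
        nodes[j].edge.length = clamp(bj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        Dn = np.zeros((len(keep) + 1, len(keep) + 1))
        Dn[: len(keep), : len(keep)] = D[np.ix_(keep, keep)]
        Dn[-1, : len(keep)] = Dn[: len(keep), -1] = dnew[keep]
        D = Dn
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final three-way join around a degree-3 central node
    center = dendropy.Node()
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].edge.length = clamp(ln)
        center.add_child(nodes[idx])

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    tree.clamped_negative_total = clamped
    return tree


# ---------------------------------------------------------------------------
# bipartitions, Robinson-Foulds


def nontrivial_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as canonical frozensets of leaf labels.

    Each internal edge splits the leaves in two; the side not containing
    the overall smallest label is stored. Splits with fewer than two labels
    on either side are trivial and omitted.
    """
    labels = leaf_labels(tree)
    anchor = min(labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if anchor in side:
            side = labels - side
        if 2 <= len(side) <= len(labels) - 2:
            out.add(frozenset(side))
    return out


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    if leaf_labels(t1) != leaf_labels(t2):
        raise ValueError("trees have different leaf label sets")
    return len(nontrivial_bipartitions(t1) ^ nontrivial_bipartitions(t2))


def is_clade(tree: dendropy.Tree, group: Iterable[str]) -> bool:
    """True if ``group`` is one side of some edge of the unrooted tree."""
    group = frozenset(group)
    labels = leaf_labels(tree)
    comp = frozenset(labels - group)
    splits = nontrivial_bipartitions(tree)
    canon = group if min(labels) not in group else comp
    return canon in splits


# ---------------------------------------------------------------------------
# bootstrap support by gene-cluster resampling


def _resample_distance(
    pa: PresenceAbsenceMatrix, rng: np.random.Generator, mode: str
) -> DistanceMatrix:
    m = len(pa.cluster_ids)
    for _ in range(1000):
        if mode == "bootstrap":
            cols = rng.integers(0, m, size=m)
        elif mode == "jackknife":
            k = max(1, int(math.floor(0.8 * m)))
            cols = rng.choice(m, size=k, replace=False)
        else:
            raise ValueError(f"unknown resampling mode {mode!r}")
        sub = PresenceAbsenceMatrix(
            genomes=list(pa.genomes),
            cluster_ids=[f"r{i:05d}" for i in range(len(cols))],
            incidence=pa.incidence[:, cols],
        )
        if np.all(sub.gene_counts() > 0):
            return distance_matrix_from_pa(sub)
    raise RuntimeError("could not draw a resample with non-empty repertoires")


def bootstrap_support(
    pa: PresenceAbsenceMatrix,
    iterations: int = 1000,
    mode: str = "bootstrap",
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree from the full matrix with resampling supports on internal edges.

    Each iteration resamples gene-cluster columns (bootstrap: with
    replacement, same count; jackknife: 80% without replacement), recomputes
    the gene-content distances and the NJ tree, and tallies its non-trivial
    bipartitions. Support for an edge of the reference tree is the fraction
    of iterations whose tree contains the same split.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    reference = neighbor_joining(distance_matrix_from_pa(pa))
    tally: dict[frozenset[str], int] = {
        split: 0 for split in nontrivial_bipartitions(reference)
    }
    rng = np.random.default_rng(seed)
    for _ in range(iterations):
        rep = neighbor_joining(_resample_distance(pa, rng, mode))
        for split in nontrivial_bipartitions(rep):
            if split in tally:
                tally[split] += 1

    labels = leaf_labels(reference)
    anchor = min(labels)
    for node in reference.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if anchor in side:
            side = labels - side
        if 2 <= len(side) <= len(labels) - 2:
            node.support = tally[frozenset(side)] / iterations
    return reference
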