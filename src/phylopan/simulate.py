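"""Synthetic genomes, marker genes and environmental samples with known truth.

The generator emulates a small clade of large dsDNA algal viruses: a dozen
genomes of a few hundred protein-coding genes each, shaped by vertical
descent plus gene loss, gene gain and horizontal transfer; a ~900-residue
single-copy marker protein evolving under WAG on the same tree; and
amplicon reads of a fixed marker window sampled across environments. Every
stage records its ground truth (tree, family memberships, event log, OTU
counts) so the downstream clustering, distance, tree and OTU code can be
tested for recovery rather than against opaque fixtures.

Gene content evolves as a continuous-time process along the tree: each
family present on a lineage is lost at rate mu per unit branch length, and
gains arrive at rate lambda, each gain being a brand-new family or, with
probability ``hgt_fraction``, a family copied from a uniformly chosen other
lineage alive at the moment of transfer. The whole-tree process is run as a
single chronological Gillespie sweep so that transfer donors are sampled
from the true contemporaneous lineages.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .cluster import PresenceAbsenceMatrix
from .marker import MarkerAlignment
from .otu import OTUTable
from .records import ProteinRecord
from .wag import SubstitutionModel, wag_model

import pandas as pd


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic clade.

    Rates are per unit branch length on a tree rescaled to height 1, so a
    loss rate of 0.3 means an ancestral family survives from root to leaf
    with probability exp(-0.3) ~ 0.74.
    """

    n_taxa: int = 12
    root_family_count: int = 240
    loss_rate: float = 0.3
    gain_rate: float = 0.3
    hgt_fraction: float = 0.2
    marker_length: int = 900
    amplicon_window: tuple[int, int] = (300, 440)
    within_family_identity: float = 0.8
    between_family_identity_max: float = 0.3
    family_length_range: tuple[int, int] = (65, 800)
    env_novel_fraction: float = 0.3
    env_lognormal_sigma: float = 1.0
    env_read_noise: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.loss_rate < 0 or self.gain_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.hgt_fraction <= 1.0:
            raise ValueError("hgt_fraction must be in [0, 1]")
        lo, hi = self.amplicon_window
        if not (0 <= lo < hi <= self.marker_length):
            raise ValueError("amplicon_window must lie within the marker")
        if not self.within_family_identity > 0.5 > self.between_family_identity_max:
            raise ValueError(
                "within-family identity must exceed the 0.5 clustering default, "
                "and between-family identity must stay below it"
            )
        if self.env_read_noise > 0.01:
            raise ValueError("per-residue read noise is capped at 1%")


@dataclass
class TruthBundle:
    """Ground truth recorded while simulating."""

    true_tree: dendropy.Tree
    family_membership: dict[str, set[str]]
    family_origin: dict[str, tuple]
    events: list[tuple] = field(default_factory=list)
    true_otu_table: OTUTable | None = None


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg_seed, stream]))


def simulate_tree(n_taxa: int, seed: int = 0) -> dendropy.Tree:
    """Yule (pure-birth) tree on ``n_taxa`` leaves, rescaled to height 1.

    Leaves are labeled G01, G02, ... in tree traversal order. Branch
    lengths are strictly positive and the tree is ultrametric.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    # the simulator stops at the instant the nth tip is born, which leaves
    # that cherry with zero-length edges; run the clock forward by the
    # waiting time to the (uninstantiated) next speciation
    extra = rng.expovariate(n_taxa)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"G{i:02d}"
    tree.seed_node.edge.length = None
    height = max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    return tree


def simulate_reference_panel(
    n_species: int,
    seed: int = 0,
    strains_per_species: int = 2,
    strain_depth_range: tuple[float, float] = (0.005, 0.03),
) -> dendropy.Tree:
    """Species tree with short terminal strain radiations.

    Emulates a marker reference panel containing both deep splits and
    near-identical strains: each leaf of a height-1 Yule species tree is
    replaced by a polytomy of strains whose depth is drawn uniformly from
    ``strain_depth_range``. Strain pairs then sit at marker distances around
    twice the strain depth, straddling typical amplicon clustering
    thresholds, while between-species distances stay large.
    """
    if strains_per_species < 1:
        raise ValueError("strains_per_species must be >= 1")
    tree = simulate_tree(n_species, seed=seed)
    rng = _rng(seed, 9)
    tns = tree.taxon_namespace
    for leaf in list(tree.leaf_node_iter()):
        base = leaf.taxon.label
        depth = float(rng.uniform(*strain_depth_range))
        depth = min(depth, 0.9 * leaf.edge.length)
        leaf.edge.length -= depth
        leaf.taxon = None
        for s in range(strains_per_species):
            taxon = tns.new_taxon(f"{base}{chr(ord('a') + s)}")
            child = dendropy.Node(taxon=taxon)
            child.edge.length = depth
            leaf.add_child(child)
    return tree


def _node_key(node: dendropy.Node) -> str:
    return min(lf.taxon.label for lf in node.leaf_iter())


def lineage_names(tree: dendropy.Tree) -> dict[int, str]:
    """Stable unique name per node: leaf label, or I<k> in preorder.

    Used to identify lineages unambiguously in the gene-content event log
    (a subtree-based key would collide between a branch and the child branch
    that carries its smallest leaf).
    """
    names: dict[int, str] = {}
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            names[id(node)] = node.taxon.label
        else:
            names[id(node)] = f"I{k:03d}"
            k += 1
    return names


def evolve_gene_content(
    tree: dendropy.Tree, cfg: SimulationConfig
) -> tuple[PresenceAbsenceMatrix, TruthBundle]:
    """Run the loss/gain/HGT process and return leaf incidence plus truth."""
    rng = _rng(cfg.seed, 1)
    mu, lam = cfg.loss_rate, cfg.gain_rate

    depth = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    root_families = [f"F{i:05d}" for i in range(cfg.root_family_count)]
    family_origin: dict[str, tuple] = {f: ("ancestral",) for f in root_families}
    counter = cfg.root_family_count
    events: list[tuple] = []

    # active edges during the sweep: child-node name -> mutable family set
    keys = lineage_names(tree)
    active: dict[str, set[str]] = {}
    node_at_depth: dict[float, list[dendropy.Node]] = {}
    for node in tree.preorder_node_iter():
        node_at_depth.setdefault(round(depth[id(node)], 12), []).append(node)
    boundaries = sorted(node_at_depth)

    leaf_sets: dict[str, set[str]] = {}

    def open_children(node: dendropy.Node, fams: set[str]) -> None:
        for child in node.child_nodes():
            active[keys[id(child)]] = set(fams)

    for b_idx, t0 in enumerate(boundaries):
        for node in node_at_depth[t0]:
            if node is tree.seed_node:
                open_children(node, set(root_families))
                continue
            arrived = active.pop(keys[id(node)])
            if node.is_leaf():
                leaf_sets[node.taxon.label] = arrived
            else:
                open_children(node, arrived)
        if b_idx + 1 >= len(boundaries):
            break
        t1 = boundaries[b_idx + 1]

        # Gillespie within (t0, t1): active lineages are fixed on this slice
        now = t0
        while active:
            labels = sorted(active)
            rates = np.array([mu * len(active[l]) + lam for l in labels])
            total = rates.sum()
            if total <= 0:
                break
            now += rng.exponential(1.0 / total)
            if now >= t1:
                break
            lab = labels[rng.choice(len(labels), p=rates / total)]
            fams = active[lab]
            if rng.random() < (mu * len(fams)) / (mu * len(fams) + lam):
                lost = sorted(fams)[rng.integers(len(fams))]
                fams.remove(lost)
                events.append((now, lab, "loss", lost, None))
            else:
                donors = [
                    l for l in labels if l != lab and active[l]
                ]
                if donors and rng.random() < cfg.hgt_fraction:
                    donor = donors[rng.integers(len(donors))]
                    fam = sorted(active[donor])[rng.integers(len(active[donor]))]
                    fams.add(fam)
                    events.append((now, lab, "hgt", fam, donor))
                else:
                    fam = f"F{counter:05d}"
                    counter += 1
                    fams.add(fam)
                    family_origin[fam] = ("gain", lab)
                    events.append((now, lab, "gain", fam, None))

    # a family's origin is the event that created it (root or a novel gain);
    # horizontal copies of existing families are recorded in the event log
    for time, lab, kind, fam, donor in events:
        if kind == "hgt" and family_origin[fam][0] == "gain":
            family_origin[fam] = ("hgt", donor, family_origin[fam][1])

    pa = PresenceAbsenceMatrix.from_membership(leaf_sets)
    truth = TruthBundle(
        true_tree=tree,
        family_membership=leaf_sets,
        family_origin=family_origin,
        events=events,
    )
    return pa, truth


def evolve_marker(
    tree: dendropy.Tree,
    cfg: SimulationConfig,
    model: SubstitutionModel | None = None,
    scale: float = 1.0,
) -> MarkerAlignment:
    """Evolve a gap-free marker protein along the tree under WAG.

    ``scale`` multiplies every branch length, letting callers tune total
    divergence without re-simulating the tree.
    """
    if cfg.marker_length < 1:
        raise ValueError("marker_length must be >= 1")
    model = model or wag_model()
    rng = _rng(cfg.seed, 2)
    states = {id(tree.seed_node): model.sample_stationary(cfg.marker_length, rng)}
    labels, seqs = [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            t = node.edge.length * scale
            parent = states[id(node.parent_node)]
            states[id(node)] = (
                parent.copy() if t == 0 else model.evolve_states(parent, t, rng)
            )
        if node.is_leaf():
            labels.append(node.taxon.label)
            seqs.append(model.states_to_str(states[id(node)]))
    return MarkerAlignment(labels=labels, sequences=seqs)


def _mutate_states(
    states: np.ndarray,
    target_identity: float,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Substitute each residue with probability 1-target_identity.

    Replacement residues are drawn from the WAG stationary frequencies
    excluding the current residue, so realized identity concentrates near
    the target.
    """
    out = states.copy()
    hit = np.flatnonzero(rng.random(len(states)) < 1.0 - target_identity)
    for i in hit:
        p = model.frequencies.copy()
        p[out[i]] = 0.0
        out[i] = rng.choice(20, p=p / p.sum())
    return out


def emit_family_sequences(
    pa: PresenceAbsenceMatrix, cfg: SimulationConfig
) -> dict[str, list[ProteinRecord]]:
    """Protein sequences for every (genome, family) incidence.

    Each family gets a random prototype (length uniform in the configured
    range, residues from WAG stationary frequencies); each genome carrying
    the family receives an independent copy mutated to approximately the
    within-family identity. Distinct families are unrelated random
    sequences, far below any sensible clustering threshold.
    """
    model = wag_model()
    rng = _rng(cfg.seed, 3)
    lo, hi = cfg.family_length_range
    out: dict[str, list[ProteinRecord]] = {g: [] for g in pa.genomes}
    for j, fam in enumerate(pa.cluster_ids):
        length = int(rng.integers(lo, hi + 1))
        proto = model.sample_stationary(length, rng)
        for i, genome in enumerate(pa.genomes):
            if pa.incidence[i, j]:
                copy = _mutate_states(proto, cfg.within_family_identity, model, rng)
                out[genome].append(
                    ProteinRecord(
                        id=f"{genome}|{fam}",
                        genome=genome,
                        sequence=model.states_to_str(copy),
                    )
                )
    return out


def simulate_environmental_samples(
    references: MarkerAlignment,
    cfg: SimulationConfig,
    n_samples: int,
    reads_per_sample: int,
) -> tuple[dict[str, list[ProteinRecord]], OTUTable]:
    """Amplicon reads per environmental sample plus the true OTU table.

    The lineage pool is the references plus novel lineages (references
    mutated to 85-95% full-length identity). Per sample, lineage abundances
    are log-normal; reads are the amplicon window of the chosen lineage
    with per-residue substitution noise.
    """
    if len(references) == 0:
        raise ValueError("references must be nonempty")
    if reads_per_sample < 1:
        raise ValueError("reads_per_sample must be >= 1")
    model = wag_model()
    rng = _rng(cfg.seed, 4)
    lo, hi = cfg.amplicon_window

    pool: list[tuple[str, np.ndarray]] = [
        (lab, model.str_to_states(seq.replace("-", "")[: cfg.marker_length]))
        for lab, seq in zip(references.labels, references.sequences)
    ]
    n_novel = int(round(cfg.env_novel_fraction * len(references)))
    for k in range(n_novel):
        src_idx = int(rng.integers(len(references)))
        ident = rng.uniform(0.85, 0.95)
        novel = _mutate_states(pool[src_idx][1], ident, model, rng)
        pool.append((f"novel{k:03d}", novel))

    samples: dict[str, list[ProteinRecord]] = {}
    truth_rows = []
    sample_names = [f"S{i:02d}" for i in range(1, n_samples + 1)]
    for sample in sample_names:
        abund = rng.lognormal(mean=0.0, sigma=cfg.env_lognormal_sigma, size=len(pool))
        counts = rng.multinomial(reads_per_sample, abund / abund.sum())
        truth_rows.append(counts)
        reads = []
        k = 0
        for (lineage, states), c in zip(pool, counts):
            window = states[lo:hi]
            for _ in range(c):
                noisy = window.copy()
                if cfg.env_read_noise > 0:
                    hit = np.flatnonzero(rng.random(len(noisy)) < cfg.env_read_noise)
                    for i in hit:
                        p = model.frequencies.copy()
                        p[noisy[i]] = 0.0
                        noisy[i] = rng.choice(20, p=p / p.sum())
                reads.append(
                    ProteinRecord(
                        id=f"{sample}|r{k:05d}",
                        genome=sample,
                        sequence=model.states_to_str(noisy),
                    )
                )
                k += 1
        samples[sample] = reads

    truth = OTUTable(
        counts=pd.DataFrame(
            truth_rows, index=sample_names, columns=[lab for lab, _ in pool]
        )
    )
    return samples, truth
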