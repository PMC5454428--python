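"""Shared fixtures: a small synthetic clade with full ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import phylopan as pp


@pytest.fixture(scope="session")
def wag():
    return pp.wag_model()


@pytest.fixture(scope="session")
def reference_matrices():
    """Packaged 13-virus reference matrices (gene content, marker)."""
    return pp.reference_distance_matrices()


@pytest.fixture(scope="session")
def small_clade():
    """Six-genome synthetic clade: tree, config, truth, incidence, proteins.

    Session-scoped because emitting and clustering a few hundred proteins
    dominates suite runtime.
    """
    cfg = pp.SimulationConfig(n_taxa=6, root_family_count=40, seed=11)
    tree = pp.simulate_tree(cfg.n_taxa, seed=11)
    pa, truth = pp.evolve_gene_content(tree, cfg)
    proteins = pp.emit_family_sequences(pa, cfg)
    return {"cfg": cfg, "tree": tree, "pa": pa, "truth": truth, "proteins": proteins}


@pytest.fixture(scope="session")
def small_clade_clusters(small_clade):
    records = [r for recs in small_clade["proteins"].values() for r in recs]
    clusters = pp.greedy_cluster(records, threshold=0.5)
    return records, clusters


def random_protein(rng: np.random.Generator, length: int) -> str:
    from phylopan.records import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def distinct_lineage_panel(
    n_taxa: int, base_seed: int, max_window_identity: float = 0.95, **cfg_kwargs
):
    """Markers on a simulated tree whose amplicon windows are OTU-distinct.

    Several tests state preconditions of the form "k distinguishable
    lineages"; a random tree draw can violate that (a late cherry leaves two
    taxa nearly identical inside the window), so seeds are scanned from
    ``base_seed`` until every pairwise window identity (plain Hamming on the
    gap-free window, independent of the alignment code under test) is at
    most ``max_window_identity``.
    """
    for seed in range(base_seed, base_seed + 50):
        tree = pp.simulate_tree(n_taxa, seed=seed)
        cfg = pp.SimulationConfig(n_taxa=n_taxa, seed=seed, **cfg_kwargs)
        msa = pp.evolve_marker(tree, cfg)
        lo, hi = cfg.amplicon_window
        windows = [s[lo:hi] for s in msa.sequences]
        ok = True
        for i in range(len(windows)):
            for j in range(i + 1, len(windows)):
                ident = np.mean(
                    [a == b for a, b in zip(windows[i], windows[j])]
                )
                if ident > max_window_identity:
                    ok = False
        if ok:
            return tree, cfg, msa
    raise RuntimeError("no distinct-lineage panel found in the scanned seed range")
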