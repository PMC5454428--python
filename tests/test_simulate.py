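"""Generator correctness: tree shape, gain/loss/HGT process, emission, samples."""

from __future__ import annotations

import numpy as np
import pytest

import phylopan as pp
from phylopan.simulate import simulate_reference_panel


class TestSimulateTree:
    def test_smallest_tree_shape(self):
        t = pp.simulate_tree(3, seed=1)
        leaves = list(t.leaf_node_iter())
        internal = [n for n in t.preorder_node_iter() if not n.is_leaf()]
        assert len(leaves) == 3
        # rooted representation: root plus one internal node = one internal edge
        assert len(internal) == 2

    def test_deterministic_given_seed(self):
        a = pp.write_newick(pp.simulate_tree(12, seed=1))
        b = pp.write_newick(pp.simulate_tree(12, seed=1))
        assert a == b
        c = pp.write_newick(pp.simulate_tree(12, seed=2))
        assert a != c

    def test_ultrametric_height_one(self):
        t = pp.simulate_tree(50, seed=3)
        depths = [lf.distance_from_root() for lf in t.leaf_node_iter()]
        assert np.mean(depths) == pytest.approx(1.0, abs=1e-9)
        assert max(depths) - min(depths) < 1e-9

    def test_positive_branch_lengths(self):
        t = pp.simulate_tree(20, seed=4)
        for e in t.preorder_edge_iter():
            if e.length is not None:
                assert e.length > 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            pp.simulate_tree(2, seed=0)


class TestEvolveGeneContent:
    def test_no_events_means_root_repertoire_everywhere(self):
        cfg = pp.SimulationConfig(
            n_taxa=5, root_family_count=37, loss_rate=0.0, gain_rate=0.0, seed=5
        )
        tree = pp.simulate_tree(5, seed=5)
        pa, truth = pp.evolve_gene_content(tree, cfg)
        assert (pa.gene_counts() == 37).all()
        d = pp.distance_matrix_from_pa(pa)
        assert np.allclose(d.values, 0.0)
        assert truth.events == []

    def test_pure_loss_expectation(self):
        """Mean leaf repertoire matches G0 * exp(-mu * depth) within 3 SE."""
        g0, mu = 100, 1.0
        counts = []
        for rep in range(200):
            cfg = pp.SimulationConfig(
                n_taxa=3, root_family_count=g0, loss_rate=mu, gain_rate=0.0,
                seed=50_000 + rep,
            )
            tree = pp.simulate_tree(3, seed=60_000 + rep)
            pa, _ = pp.evolve_gene_content(tree, cfg)
            counts.append(pa.gene_counts()[0])  # one leaf per replicate: independent
        p = np.exp(-mu)  # every leaf sits at depth 1
        expected = g0 * p
        se = np.sqrt(g0 * p * (1 - p) / len(counts))
        assert abs(np.mean(counts) - expected) <= 3 * se

    def test_hgt_events_replay_consistently(self):
        """Replaying the event log reproduces leaf repertoires, and every
        transfer's family was present on the donor lineage at that time."""
        cfg = pp.SimulationConfig(
            n_taxa=8, root_family_count=60, loss_rate=0.4, gain_rate=2.0,
            hgt_fraction=1.0, seed=7,
        )
        tree = pp.simulate_tree(8, seed=7)
        pa, truth = pp.evolve_gene_content(tree, cfg)
        assert any(e[2] == "hgt" for e in truth.events)

        # independent replay over the tree, applying recorded events
        from phylopan.simulate import lineage_names

        names = lineage_names(tree)
        depth = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            depth[id(node)] = 0.0 if parent is None else depth[id(parent)] + node.edge.length

        segments = {}  # name -> (t_start, t_end, parent_name or None)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                segments[names[id(node)]] = (
                    depth[id(node.parent_node)],
                    depth[id(node)],
                    None
                    if node.parent_node is tree.seed_node
                    else names[id(node.parent_node)],
                )

        root_set = {f for f, o in truth.family_origin.items() if o[0] == "ancestral"}
        events_by_lineage = {}
        for ev in truth.events:
            events_by_lineage.setdefault(ev[1], []).append(ev)

        def set_at(lineage_key, time):
            """Family set of a lineage segment at a given time, by replay."""
            t0, t1, parent = segments[lineage_key]
            base = set(root_set) if parent is None else set_at(parent, t0)
            s = set(base)
            for ev in events_by_lineage.get(lineage_key, []):
                if ev[0] > time:
                    continue
                if ev[2] == "loss":
                    s.discard(ev[3])
                else:
                    s.add(ev[3])
            return s

        for leaf in tree.leaf_node_iter():
            lab = leaf.taxon.label
            assert set_at(lab, depth[id(leaf)] + 1) == truth.family_membership[lab]

        for t, lab, kind, fam, donor in truth.events:
            if kind == "hgt":
                assert fam in set_at(donor, t)

    def test_determinism(self):
        cfg = pp.SimulationConfig(n_taxa=6, root_family_count=50, seed=9)
        tree = pp.simulate_tree(6, seed=9)
        pa1, _ = pp.evolve_gene_content(tree, cfg)
        pa2, _ = pp.evolve_gene_content(tree, cfg)
        assert pa1.cluster_ids == pa2.cluster_ids
        assert (pa1.incidence == pa2.incidence).all()


class TestEvolveMarker:
    def test_zero_branch_lengths_keep_root_sequence(self):
        tree = pp.simulate_tree(4, seed=11)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = 0.0
        cfg = pp.SimulationConfig(
            n_taxa=4, marker_length=200, amplicon_window=(30, 170), seed=11
        )
        msa = pp.evolve_marker(tree, cfg)
        assert len(set(msa.sequences)) == 1

    def test_gap_free_alignment_of_configured_length(self):
        cfg = pp.SimulationConfig(
            n_taxa=5, marker_length=300, amplicon_window=(30, 170), seed=12
        )
        msa = pp.evolve_marker(pp.simulate_tree(5, seed=12), cfg)
        assert msa.n_columns == 300
        assert all("-" not in s for s in msa.sequences)

    def test_two_leaf_path_distance_recovered(self):
        """Pairwise ML distance is consistent for the leaf-to-leaf path."""
        tree = pp.simulate_tree(3, seed=13)
        cfg = pp.SimulationConfig(n_taxa=3, marker_length=2000, seed=13)
        msa = pp.evolve_marker(tree, cfg, scale=0.25)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = msa.labels[i], msa.labels[j]
                t_true = 0.25 * pdm.patristic_distance(taxa[a], taxa[b])
                t_hat = pp.pairwise_ml_distance(msa.get(a), msa.get(b))
                se = np.sqrt(max(t_true, 0.05) / 2000)  # Poisson-scale error
                assert abs(t_hat - t_true) <= 4 * se


class TestEmitFamilySequences:
    def test_perfect_identity_gives_identical_copies(self):
        cfg = pp.SimulationConfig(
            n_taxa=4, root_family_count=10, loss_rate=0.0, gain_rate=0.0,
            within_family_identity=1.0, seed=14,
        )
        tree = pp.simulate_tree(4, seed=14)
        pa, _ = pp.evolve_gene_content(tree, cfg)
        seqs = pp.emit_family_sequences(pa, cfg)
        by_family = {}
        for recs in seqs.values():
            for r in recs:
                by_family.setdefault(r.id.split("|")[1], set()).add(r.sequence)
        assert all(len(v) == 1 for v in by_family.values())

    def test_between_family_identity_stays_low(self, small_clade):
        proteins = small_clade["proteins"]
        rng = np.random.default_rng(15)
        by_family = {}
        for recs in proteins.values():
            for r in recs:
                by_family.setdefault(r.id.split("|")[1], r)
        fams = sorted(by_family)
        for _ in range(30):
            i, j = rng.choice(len(fams), size=2, replace=False)
            ident = pp.pairwise_identity(
                by_family[fams[i]].sequence, by_family[fams[j]].sequence
            )
            assert ident <= small_clade["cfg"].between_family_identity_max

    def test_shared_counts_reflect_construction(self):
        membership = {g: {f"fam{i}" for i in range(10)} for g in ("g1", "g2", "g3")}
        pa = pp.PresenceAbsenceMatrix.from_membership(membership)
        counts = pp.shared_counts(pa)
        assert counts["all"] == 10

    def test_respects_length_bounds(self, small_clade):
        lo, hi = small_clade["cfg"].family_length_range
        for recs in small_clade["proteins"].values():
            for r in recs:
                assert lo <= len(r) <= hi


class TestEnvironmentalSamples:
    def test_noise_free_single_lineage_one_otu(self, wag):
        rng = np.random.default_rng(16)
        seq = wag.states_to_str(wag.sample_stationary(900, rng))
        refs = pp.MarkerAlignment(labels=["ref"], sequences=[seq])
        cfg = pp.SimulationConfig(
            n_taxa=3, seed=16, env_read_noise=0.0, env_novel_fraction=0.0
        )
        samples, truth = pp.simulate_environmental_samples(
            refs, cfg, n_samples=2, reads_per_sample=20
        )
        reads = [r for rs in samples.values() for r in rs]
        assert len({r.sequence for r in reads}) == 1
        assert len(pp.otu_cluster(reads, threshold=0.97)) == 1

    def test_amplicon_window_length(self):
        tree = pp.simulate_tree(4, seed=17)
        cfg = pp.SimulationConfig(n_taxa=4, seed=17)
        msa = pp.evolve_marker(tree, cfg)
        samples, _ = pp.simulate_environmental_samples(
            msa, cfg, n_samples=1, reads_per_sample=5
        )
        lo, hi = cfg.amplicon_window
        for r in samples["S01"]:
            assert len(r) == hi - lo

    def test_equal_depth_rarefaction_noop(self):
        tree = pp.simulate_tree(4, seed=18)
        cfg = pp.SimulationConfig(n_taxa=4, seed=18)
        msa = pp.evolve_marker(tree, cfg)
        _, truth = pp.simulate_environmental_samples(
            msa, cfg, n_samples=5, reads_per_sample=100
        )
        r = pp.rarefy(truth, seed=1)
        assert (r.counts.values == truth.counts.values).all()

    def test_invalid_depth_rejected(self):
        tree = pp.simulate_tree(4, seed=19)
        cfg = pp.SimulationConfig(n_taxa=4, seed=19)
        msa = pp.evolve_marker(tree, cfg)
        with pytest.raises(ValueError):
            pp.simulate_environmental_samples(msa, cfg, n_samples=1, reads_per_sample=0)

    def test_determinism(self):
        tree = pp.simulate_tree(4, seed=20)
        cfg = pp.SimulationConfig(n_taxa=4, seed=20)
        msa = pp.evolve_marker(tree, cfg)
        s1, t1 = pp.simulate_environmental_samples(msa, cfg, 2, 30)
        s2, t2 = pp.simulate_environmental_samples(msa, cfg, 2, 30)
        assert (t1.counts.values == t2.counts.values).all()
        assert [r.sequence for r in s1["S01"]] == [r.sequence for r in s2["S01"]]


class TestReferencePanel:
    def test_strain_pairs_are_shallow_and_ultrametric(self):
        t = simulate_reference_panel(6, seed=21, strains_per_species=2)
        assert sum(1 for _ in t.leaf_node_iter()) == 12
        depths = [lf.distance_from_root() for lf in t.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_taxa": 2},
            {"loss_rate": -0.1},
            {"hgt_fraction": 1.5},
            {"amplicon_window": (800, 950)},
            {"within_family_identity": 0.4},
            {"env_read_noise": 0.05},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            pp.SimulationConfig(**kwargs)
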