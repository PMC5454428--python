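# phylopan

Gene-content phylogenetics and marker-gene congruence for large dsDNA algal
viruses (prasinoviruses and chloroviruses, family *Phycodnaviridae*), and for
any comparable set of small genomes.

## The problem

Prasinoviruses infecting *Micromonas*, *Ostreococcus* and *Bathyococcus*
share a compact core genome but differ strongly in a flexible pan-genome
shaped by gene loss, gain and horizontal transfer. Whole-genome comparisons
can place sequenced isolates on a tree by what their genomes *contain*, but
environmental surveys only see PCR fragments of a single conserved marker
(family-B DNA polymerase, DNApol). The question this package operationalizes:
**is the marker phylogeny a faithful proxy for gene content**, and at what
amplicon identity threshold do marker fragments stand in for full-length
sequences?

## What it computes

- **Gene clusters.** Proteins pooled across genomes are clustered greedily at
  a fractional amino-acid identity threshold (default 50%): records are
  processed longest-first, each joining the first centroid it matches at or
  above the threshold (UCLUST-style). Identity is BLAST-like: one optimal
  global alignment (BLOSUM62, affine gaps −11/−1), identical residue pairs
  over alignment columns, terminal gaps excluded.
- **Gene-content distance.** From the genome × cluster incidence matrix,
  with S_ij shared clusters and N_i, N_j cluster counts,

      D_ij = −ln( S_ij / √(N_i · N_j) )

  (S_ij = 0 is capped with a 0.5 pseudo-count and flagged).
- **Trees.** Saitou–Nei neighbor joining with deterministic tie-breaking,
  plus bipartition supports from resampling gene-cluster columns
  (bootstrap, or 80% jackknife).
- **Marker distances.** Pairwise maximum-likelihood distances under the WAG
  amino-acid model: t̂ = argmax Σ_sites ln(π_x P_xy(t)), with P(t) = e^{Qt}
  by eigendecomposition and pairwise gap deletion.
- **Congruence.** Mantel test between the two distance matrices (Pearson on
  strict lower triangles, permutation p-value).
- **Calibration.** For a grid of amplicon identity thresholds, the standard
  deviation of full-length marker distances pooled within amplicon clusters;
  the chosen threshold is the smallest one whose spread drops below a
  tolerance (default 0.05).
- **OTUs.** Environmental amplicon reads pooled with references, clustered
  at 97% identity with references seeded as the first centroids, singletons
  discarded, reads assigned to their best centroid, and the sample × OTU
  table rarefied without replacement to the minimum sample depth.
- **Synthetic data.** A generator producing genomes (gene repertoires under
  a loss/gain/HGT process along a Yule tree, with protein sequences), a
  ~900-residue WAG marker on the same tree, amplicon windows, and
  environmental samples — all with recorded ground truth, so every stage is
  testable for recovery.

## Worked example

The package ships the published 13-virus reference matrices (gene
presence-absence distances above the diagonal, full-length DNApol WAG
distances below it) as a fixture:

```python
import phylopan as pp

pa_d, dnapol = pp.reference_distance_matrices()
res = pp.mantel_test(pa_d, dnapol, permutations=999, seed=1)
print(f"Mantel r (13 viruses) = {res.r:.4f}, p = {res.p:.4f}")

keep = [l for l in pa_d.labels if l not in ("PBCV1", "AR158")]
res11 = pp.mantel_test(pp.subset_matrix(pa_d, keep),
                       pp.subset_matrix(dnapol, keep),
                       permutations=999, seed=1)
print(f"Mantel r (11 prasinoviruses) = {res11.r:.4f}, p = {res11.p:.4f}")

d, _ = pp.gene_content_distance(125, 271, 260)   # MpV-PL1 vs OtV5
print(f"D(MpV-PL1, OtV5) = {d:.4f}")

tree = pp.neighbor_joining(pa_d)
print(pp.is_clade(tree, ("MpV-PL1", "MpV-SP1")))
```

prints

```
Mantel r (13 viruses) = 0.9961, p = 0.0010
Mantel r (11 prasinoviruses) = 0.9642, p = 0.0010
D(MpV-PL1, OtV5) = 0.7531
True
```

The two r values mean the marker distances explain essentially all of the
variation in gene-content distances, with or without the chlorovirus
outgroup; D(MpV-PL1, OtV5) = 0.75 reproduces the corresponding
presence-absence cell of the reference matrix; and the neighbor-joining tree
groups the two *Micromonas pusilla* viruses (as well as the *Bathyococcus*
and *Chlorella* virus pairs) exactly as the published genome comparison does.

The same operations are available from the shell:

```
phylopan simulate --outdir demo --seed 5
phylopan cluster --identity 0.5 --out clusters.tsv demo/genomes/*.faa
phylopan pamatrix clusters.tsv > pa.tsv
phylopan distance pa.tsv > dij.tsv
phylopan njtree dij.tsv > tree.nwk
phylopan bootstrap pa.tsv --iterations 1000 --seed 7 > tree_supported.nwk
phylopan markerdist demo/marker.faa > dnapol.tsv
phylopan mantel dij.tsv dnapol.tsv --permutations 999 --seed 1
phylopan otu --identity 0.97 --out otu.tsv --seed 11 demo/samples/*.faa
phylopan rarefy otu.tsv --seed 3
```

## Layout

| module | contents |
| --- | --- |
| `phylopan.records` | protein records, FASTA I/O |
| `phylopan.align` | global alignment, BLAST-like identity |
| `phylopan.cluster` | greedy clustering, presence-absence, core/pan, Venn counts |
| `phylopan.distance` | D_ij, labeled distance matrices |
| `phylopan.tree` | neighbor joining, Robinson–Foulds, bootstrap supports, Newick |
| `phylopan.wag` | WAG substitution model |
| `phylopan.marker` | pairwise ML distances, corrected distances, amplicons |
| `phylopan.congruence` | Mantel test, threshold calibration |
| `phylopan.otu` | OTU clustering, assignment, rarefaction |
| `phylopan.simulate` | synthetic clades, markers, environmental samples |
| `phylopan.cli` | `phylopan` command-line entry point |

See `docs/methods.md` for the models, assumptions and numerical choices.
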