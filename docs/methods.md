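# Methods

This note records the models behind `phylopan`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
numerical and design choices made where more than one convention was
defensible.

## Sequence identity and clustering

Pairwise identity is defined operationally, the way centroid-clustering
tools define it: compute one optimal global alignment under BLOSUM62 with
affine gap costs (open −11, extend −1; a gap of length k costs
open + (k−1)·extend, Biopython's convention), then divide the number of
identically matched residue pairs by the number of alignment columns inside
the region covered by both sequences. Terminal-gap columns are excluded from
the denominator; internal gap columns count as mismatches; `X` never counts
as a match (conservative). Because an optimal alignment need not be unique
and the aligner's choice among co-optimal alignments depends on argument
order, the pair is put in a canonical order (longer sequence first, ties by
lexicographic comparison) before aligning, which makes identity exactly
symmetric.

Greedy clustering processes records longest-first (ties by identifier) and
joins each record to the first centroid, in creation order, that it matches
at or above the threshold; otherwise the record founds a new cluster. The
default threshold is 0.5, matching the usual cut-off for calling viral
protein homologues. The greedy rule guarantees members are within the
threshold of their centroid but not that centroids are mutually below it.
No query-coverage constraint is applied on top of identity.

A pre-screen skips alignments that cannot reach the threshold: with
Levenshtein distance `lev` (computed by edlib), any global alignment has at
most (|a|+|b|−lev)/2 matches and the identity denominator is at least
min(|a|,|b|), so `(|a|+|b|−lev) / (2·min(|a|,|b|))` bounds the achievable
identity from above. The bound is exact-safe: clustering output is identical
with the pre-screen on or off (covered by a test).

Multi-copy genes collapse to a single presence in the incidence matrix;
copy numbers remain visible in the cluster table. The core genome is the
set of clusters present in every genome, with no annotation-based
augmentation; everything else is the pan (flexible) genome.

## Gene-content distance and trees

For genomes i, j with repertoire sizes N_i, N_j and S_ij shared clusters,

    D_ij = −ln( S_ij / √(N_i · N_j) ).

Identical repertoires give 0. S_ij = 0 would be infinite, so it is capped
with a pseudo-count of 0.5 and the pair is flagged; flagged pairs are
reported alongside the matrix. D is not guaranteed to be metric or
additive; neighbor joining is applied to it regardless, which is standard
practice for gene-content phylogenies.

Neighbor joining is the classic Saitou–Nei agglomeration on the
Q-criterion. Exact ties in Q are broken by the lexicographically smallest
pair of node keys (a node's key is its smallest descendant leaf label), so
output is deterministic. Negative branch lengths are clamped to zero and
the total clamped deficit is kept on the tree object. Under a pure-loss
model the expected distance is affine in the patristic distance
(E[D_ij] ≈ μ/2 × d_tree), so NJ is consistent for the simulator's regime;
on additive inputs the implementation recovers the generating tree exactly
(tested against brute-force enumeration and scikit-bio's NJ).

Branch support comes from resampling gene-cluster columns: bootstrap
(with replacement, same column count; default) or jackknife (80% without
replacement, flagged alternative). Each replicate recomputes D and the NJ
tree; support for an edge of the reference tree is the fraction of
replicates containing the same bipartition. A replicate in which some
genome draws zero columns has no defined D and is redrawn; at realistic
repertoire sizes (hundreds of clusters) this is vanishingly rare.
Robinson–Foulds distance is the size of the symmetric difference of
non-trivial bipartitions (cross-checked against dendropy). Newick output
uses a canonical child ordering (smallest descendant leaf label), making
write → read → write idempotent.

## Marker distances under WAG

WAG is an empirical reversible amino-acid model: symmetric
exchangeabilities S and stationary frequencies π, rate matrix
Q_ij = S_ij·π_j normalized to one expected substitution per site per unit
time. The numerical values are the published ones, shipped in
`data/wag.dat` with a pinned sha256. P(t) = e^{Qt} is computed from the
eigendecomposition of the symmetrized generator, which is exact for a
20-state reversible chain; rows of P sum to 1 to 1e−10 and detailed balance
holds to the same tolerance (tested).

The pairwise distance between two aligned sequences maximizes
Σ_sites ln(π_x · P_xy(t)) over t ∈ [1e−6, 20] by bounded Brent search
(xatol 1e−8), using a 20×20 site-pattern count matrix for speed. Columns
with a gap or `X` in either sequence are dropped for that pair only
(pairwise deletion — it keeps the most signal per pair; complete deletion
would discard columns globally). No among-site rate variation is modeled
(no +Γ); the congruence analysis consumes relative distances, for which the
plain model suffices, and a gamma extension would slot into the same
`SubstitutionModel` surface. p-distance and Poisson-corrected
(−ln(1−p)) distances are provided as fast cross-checks.

This package deliberately computes pairwise ML distances + NJ rather than a
full ML tree search: the congruence statistic (Mantel) consumes distance
matrices, and the packaged reference marker matrix is itself a distance
matrix, so a tree-search engine would add machinery without changing any
downstream quantity. Exact reproduction of a particular tree-search
program's distances is therefore not claimed.

An "amplicon" is a fixed half-open column window of the marker alignment,
default [300, 440) — 140 residues, the length of the fragment the standard
DNApol assay recovers. The true primer coordinates within the gene are not
published; the window position is configurable and no claim is made that
the default matches the physical primers. Environmental reads are often
slightly shorter (~129 aa); trimmed reads still anchor to their source
reference at 97% because terminal gaps are excluded from identity.

## Mantel congruence

The Mantel statistic is the Pearson correlation of the strict lower
triangles of two labeled distance matrices after aligning label order; the
permutation p-value permutes one matrix's labels
(p = (#{r_perm ≥ r_obs}+1)/(perms+1), upper tail, default 999
permutations). Pearson (not Spearman) is the default because it reproduces
the published correlations for the packaged reference matrices. The r
statistic itself is permutation-free, so seeds affect only p.

Recomputing from the packaged 13-virus matrices gives r = 0.9961 with all
taxa and r = 0.9642 for the 11 prasinoviruses. The corresponding published
values, 0.99 and 0.96, match both recomputed values under truncation to two
decimals (0.9961 would round to 1.00); the tests record the recomputed
values and their truncation-consistency explicitly.

## Threshold calibration

For each threshold g in a grid (default 0.70–1.00, step 0.01), the amplicon
sequences are greedily clustered at g and the full-length marker distances
among co-clustered taxa are pooled over all clusters with ≥ 2 members; the
curve reports the sample (n−1) standard deviation and the pair count, with
the spread undefined (reported missing) when fewer than two pairs
contribute. The selected threshold is the smallest g with spread ≤ ε
(default ε = 0.05 on the WAG-distance scale); if none qualifies, the
minimizer is returned with a flag. On synthetic reference panels containing
strain-level radiations the spread shrinks with stringency and is well
below 0.05 at g = 0.97, mirroring the behavior that motivates clustering
environmental DNApol fragments at 97% amino-acid identity.

## OTU analysis

Reads from all samples are pooled with the reference amplicons; references
are seeded as the first centroids so reference-anchored OTUs keep stable
identifiers (the pooling order is otherwise unspecified in common
practice). Exact duplicates are collapsed before alignment and re-expanded
afterwards. Clusters with a single member are discarded; a reference seed
with no reads counts as a singleton and is kept only on request. Reads are
then assigned to the best-identity centroid at ≥ 97% (ties to the earliest
centroid); unassigned reads are counted per sample. Rarefaction subsamples
every sample without replacement (multivariate hypergeometric) to the
minimum sample depth — the `rrarefy` semantics of community-ecology
practice — and is deterministic per seed. Upstream read denoising and
chimera removal are out of scope; inputs are assumed to be clean amino-acid
reads.

## The synthetic-data generator

The generator emulates a clade like the sequenced prasinoviruses: about a
dozen genomes of a few hundred gene families each, a shared core eroded by
loss, a flexible genome fed by gain and horizontal transfer, and a
single-copy ~900-residue marker evolving on the same history.

- **Tree.** Pure-birth (Yule) with unit rate, conditioned on the leaf
  count, extended by the exponential waiting time to the next
  (uninstantiated) speciation so no edge has length zero, and rescaled to
  height 1. Rates below are therefore per total tree depth.
- **Gene content.** Each family present on a lineage is lost at rate μ
  (default 0.3); gains arrive at rate λ (default 0.3), each being novel
  with probability 1−h or copied from a uniformly chosen other lineage
  alive at that instant with probability h (default h = 0.2). The whole
  tree is run as one chronological Gillespie sweep so transfer donors are
  sampled from the true contemporaneous lineages; per-branch, losses are
  exactly the 1−e^{−μt} thinning of the repertoire and gains are
  Poisson(λt). The event log records every loss, gain and transfer with
  its time, lineage and donor, and an independent replay of the log
  reproduces the leaf repertoires (tested). A family's recorded origin is
  the event that created it (ancestral or novel gain, with first transfer
  donor noted); if every other lineage happened to have an empty
  repertoire at a transfer instant the gain falls back to a novel family.
  With defaults (240 root families), leaves carry roughly 180–250
  families, the scale of real prasinovirus gene repertoires.
- **Family sequences.** Each family gets a random prototype (length
  uniform in [65, 800] residues — the lower bound is the usual minimum ORF
  call — residues from WAG frequencies); each genome carrying the family
  receives a copy substituted per-residue with probability 1 − 0.8, the
  replacement drawn from WAG frequencies excluding the current residue.
  Within-family identities therefore concentrate near 0.8 (member pairs
  near 0.65), and unrelated families align at ≲ 0.2 identity, so the 0.5
  clustering threshold sits in a wide empty margin and greedy clustering
  recovers the planted partition exactly (adjusted Rand index 1, tested).
- **Marker.** Root sequence from WAG stationary frequencies; sites evolve
  independently along each branch via P(t); no indels, so leaves form a
  gap-free alignment. A scale factor multiplies branch lengths to set total
  divergence without re-simulating the tree.
- **Environmental samples.** The lineage pool is the references plus novel
  lineages (references mutated to 85–95% full-length identity, emulating
  unsequenced relatives). Per sample, lineage abundances are log-normal
  (σ = 1); reads are the amplicon window of the chosen lineage with
  per-residue substitution noise (default 0.5%, capped at 1%). The true
  sample × lineage counts are returned as the ground-truth OTU table.
- **Reference panels for calibration.** `simulate_reference_panel` grafts
  short terminal strain radiations (depth uniform in [0.005, 0.03]) onto a
  Yule species tree, reproducing the structure of real marker panels —
  deep splits plus near-identical strains — which is what makes an identity
  threshold calibratable in the first place.

What the generator does **not** emulate: nucleotide-level evolution and
codon structure, indels (real aligned markers have gaps; the pipeline
handles them, the generator never produces them), gene duplication
(multi-copy families), rate heterogeneity across sites or lineages,
sequencing error profiles beyond uniform substitution noise, chimeras, and
any correlation between gene content and environment. Passing recovery
tests on this generator therefore demonstrates correctness of the
algorithms under the stated model, not robustness to alignment error or
real sequencing artifacts.

All generator operations are deterministic given the configuration seed;
independent random streams are derived per operation from that seed.

## Problem sizes used in the shipped checks

The recovery and calibration checks run at sizes chosen to exercise the
statistics without waste: clustering recovery on 6 genomes × 40 root
families at the default identity settings and full length range; NJ
consistency on 100 random trees of 4–10 taxa; gene-content recovery on 50
replicates of 12 taxa × 150 root families at μ = λ = 0.3, h = 0.2; marker
recovery on 50 replicates of 8 taxa × 900 residues with divergence scaled
so the largest pairwise distance is ≈ 1; Mantel null calibration on 500
replicates of 10-taxon matrices with 199 permutations (p granularity 1/200
around the 0.05 level); threshold calibration on an 8-species × 2-strain
panel.

## Known limitations

- Unit-height Yule trees routinely contain internal edges of length ~0.02.
  At 150 root families and event rates 0.3, such an edge carries less than
  one expected gene event, and at 900 marker sites it sits at the
  resolution limit of the distance estimator — so exact topology recovery
  from a single data layer fails on a substantial minority of random
  trees. This is a property of the data regime, not of the estimators
  (NJ on expected distances recovers every tree exactly), and the shipped
  checks report it rather than hide it.
- The greedy clustering result depends on input ordering by construction;
  the packaged ordering (length, then identifier) is deterministic but not
  the only defensible one.
- The Sij = 0 cap (pseudo-count 0.5) is arbitrary to a constant; it only
  affects pairs with no detected homologues, which are flagged.
- Mantel permutation p-values assume exchangeable labels under the null;
  with strongly structured matrices the test is anti-conservative, which
  is why the package also reports the permutation-free r.
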