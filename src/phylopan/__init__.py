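"""phylopan: gene-content phylogenetics and marker-gene congruence for viruses.

The package links what a virus genome *contains* (its gene-cluster
repertoire) to where a conserved marker gene places it on a tree: proteins
are clustered into gene families at a fractional identity threshold, the
presence-absence profile yields pairwise distances and a neighbor-joining
tree with cluster-resampling supports, marker proteins yield pairwise
maximum-likelihood WAG distances, and a Mantel test quantifies how well the
marker phylogeny predicts gene content. A calibration procedure picks the
amplicon identity threshold at which marker fragments are faithful proxies
for full-length sequences, and an OTU pipeline applies that threshold to
environmental amplicon reads.
"""

from importlib import resources

from .align import global_align, pairwise_identity
from .cluster import (
    GeneCluster,
    GeneClusterSet,
    PresenceAbsenceMatrix,
    build_presence_absence,
    core_pan_partition,
    greedy_cluster,
    shared_counts,
)
from .congruence import (
    CalibrationCurve,
    MantelResult,
    calibration_curve,
    mantel_test,
    select_threshold,
)
from .distance import (
    DistanceMatrix,
    distance_matrix_from_pa,
    gene_content_distance,
    subset_matrix,
)
from .marker import (
    MarkerAlignment,
    UndefinedDistanceError,
    corrected_distance,
    extract_amplicon,
    marker_distance_matrix,
    pairwise_ml_distance,
)
from .otu import (
    OTUTable,
    assign_reads,
    discard_singletons,
    dominant_otus,
    otu_cluster,
    rarefy,
)
from .records import ProteinRecord, read_fasta, write_fasta
from .simulate import (
    SimulationConfig,
    TruthBundle,
    emit_family_sequences,
    evolve_gene_content,
    evolve_marker,
    simulate_environmental_samples,
    simulate_tree,
)
from .tree import (
    bootstrap_support,
    is_clade,
    neighbor_joining,
    nontrivial_bipartitions,
    read_newick,
    robinson_foulds,
    write_newick,
)
from .wag import SubstitutionModel, wag_model

__version__ = "0.1.0"


def reference_distance_matrices() -> tuple[DistanceMatrix, DistanceMatrix]:
    """The packaged 13-virus reference matrices (gene content, marker).

    Pairwise distances among 11 prasinovirus and 2 chlorovirus reference
    genomes: gene presence-absence distances and full-length DNA-polymerase
    WAG distances, transcribed from the published genome comparison.
    """
    base = resources.files("phylopan") / "data"
    with resources.as_file(base / "reference_gene_content_distances.tsv") as p:
        pa = DistanceMatrix.from_tsv(p)
    with resources.as_file(base / "reference_dnapol_distances.tsv") as p:
        dnapol = DistanceMatrix.from_tsv(p)
    return pa, dnapol


def reference_cds_counts() -> dict[str, int]:
    """Per-genome CDS cluster counts for the 13 reference viruses."""
    text = (resources.files("phylopan") / "data" / "reference_cds_counts.tsv").read_text()
    out = {}
    for line in text.splitlines()[1:]:
        name, n = line.split("\t")
        out[name] = int(n)
    return out
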