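"""mimicscan: screen microbial proteomes for molecular mimics of a self-epitope.

The package implements an in-silico molecular-mimicry screen built around a
TCR-binding-footprint motif: a self-peptide (by default MOG 35-55, the
encephalitogenic myelin epitope) is reduced to the handful of residues the MHC
class II molecule and the T-cell receptor actually contact, microbial protein
collections are scanned for peptides that conserve those residues at the same
spacing, candidate ligand windows are truncated and chopped into 9-mer binding
cores, and structure-prediction confidence scores (pLDDT / inter-chain PAE)
triage the cores into MHC II binders. Downstream profiling summarises hits by
phylum (normalised per genome), builds position-frequency matrices and logo
groups, and ranks candidates by four selection criteria.
"""

from mimicscan.analog import (
    AnalogHit,
    EpitopeQuery,
    evalue_from_score,
    human_mog35_55,
    local_align,
    mouse_mog35_55,
    search_analogs,
)
from mimicscan.io import (
    AlignmentHitRow,
    ConfidenceRecord,
    ProteinRecord,
    TaxonAssignment,
    TcrDockRecord,
    ingest_alignment_hits,
    read_fasta,
    read_score_tables,
    read_taxonomy_table,
    write_fasta,
)
from mimicscan.motifs import (
    CoreCandidate,
    FootprintMotif,
    LigandWindow,
    MotifMatch,
    build_motifs,
    dedup_ligands,
    enumerate_cores,
    scan_motifs,
    truncate_window,
)
from mimicscan.profiling import (
    group_logos_by_start,
    phylum_profile,
    position_frequency_matrix,
    prioritize,
)
from mimicscan.triage import (
    BestModel,
    BinderCall,
    TriageThresholds,
    classify_binder,
    classify_binders,
    modeled_fraction,
    select_best_model,
)

__version__ = "0.1.0"

__all__ = [
    "AnalogHit",
    "AlignmentHitRow",
    "BestModel",
    "BinderCall",
    "ConfidenceRecord",
    "CoreCandidate",
    "EpitopeQuery",
    "FootprintMotif",
    "LigandWindow",
    "MotifMatch",
    "ProteinRecord",
    "TaxonAssignment",
    "TcrDockRecord",
    "TriageThresholds",
    "build_motifs",
    "classify_binder",
    "classify_binders",
    "dedup_ligands",
    "enumerate_cores",
    "evalue_from_score",
    "group_logos_by_start",
    "human_mog35_55",
    "ingest_alignment_hits",
    "local_align",
    "modeled_fraction",
    "mouse_mog35_55",
    "phylum_profile",
    "position_frequency_matrix",
    "prioritize",
    "read_fasta",
    "read_score_tables",
    "read_taxonomy_table",
    "scan_motifs",
    "search_analogs",
    "select_best_model",
    "truncate_window",
    "write_fasta",
]
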