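"""Downstream profiling: taxonomy, position-frequency matrices, prioritization.

Three products: (1) per-phylum motif-analog rates, normalised by the number of
genomes each phylum contributes to the corpus, with small phyla (fewer than 10
genomes) and unclassified contigs pooled into "Others"; (2) position-frequency
matrices over the 11-mer binder windows (columns loc_0..loc_10, loc_1..loc_9
being the binding core) and per-start-residue logo groups; (3) the
four-criterion candidate prioritization used to pick peptides for validation.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mimicscan.io import AMINO_ACIDS, TaxonAssignment, UNCLASSIFIED
from mimicscan.motifs import CoreCandidate, LigandWindow, MotifMatch
from mimicscan.triage import BinderCall

logger = logging.getLogger("mimicscan")

OTHERS = "Others"
DEFAULT_MIN_GENOMES = 10
#: Core start residues of the noncanonical binding motifs most enriched
#: among predicted binders.
NONCANONICAL_STARTS = frozenset("FL")

PFM_COLUMNS = [f"loc_{i}" for i in range(11)]


def phylum_profile(
    matches: Sequence[MotifMatch],
    taxonomy: Sequence[TaxonAssignment],
    min_genomes: int = DEFAULT_MIN_GENOMES,
) -> pd.DataFrame:
    """Per-(phylum, motif) analog counts and per-genome rates.

    The genome count of a phylum is the number of genomes assigned to it in
    the taxonomy table, not only motif-bearing genomes. Phyla with fewer than
    ``min_genomes`` genomes, plus UNCLASSIFIED assignments and matches whose
    genome is absent from the table, are pooled into "Others"; counts and
    genome counts are summed before rates are computed.

    Returns a long-format frame with columns phylum, motif_id, analog_count,
    genome_count, rate — one row per (phylum, motif) with at least one analog,
    plus zero-count rows are omitted.
    """
    phylum_of = {t.genome_id: t.phylum for t in taxonomy}
    genome_counts: dict[str, int] = defaultdict(int)
    for t in taxonomy:
        genome_counts[t.phylum] += 1

    pooled = {
        ph for ph, n in genome_counts.items()
        if n < min_genomes or ph == UNCLASSIFIED
    }

    def bucket(phylum: str) -> str:
        return OTHERS if (phylum in pooled or phylum == UNCLASSIFIED) else phylum

    analog_counts: dict[tuple[str, str], int] = defaultdict(int)
    for m in matches:
        phylum = phylum_of.get(m.genome_id, UNCLASSIFIED)
        analog_counts[(bucket(phylum), m.motif_id)] += 1

    pooled_genomes = sum(genome_counts[ph] for ph in pooled)
    bucket_genomes: dict[str, int] = {
        ph: n for ph, n in genome_counts.items() if ph not in pooled
    }
    if pooled_genomes or any(b == OTHERS for b, _ in analog_counts):
        bucket_genomes[OTHERS] = pooled_genomes

    rows = []
    for (phylum, motif_id), count in sorted(analog_counts.items()):
        genomes = bucket_genomes.get(phylum, 0)
        rate = count / genomes if genomes else float("nan")
        if genomes == 0:
            logger.warning(
                "phylum %s has analogs but zero genomes in the table", phylum
            )
        rows.append((phylum, motif_id, count, genomes, rate))
    return pd.DataFrame(
        rows, columns=["phylum", "motif_id", "analog_count", "genome_count", "rate"]
    )


def position_frequency_matrix(
    candidates: Sequence[CoreCandidate],
) -> pd.DataFrame:
    """Empirical residue frequencies at each of the 11 window positions.

    Rows are the 20 canonical residues, columns loc_0..loc_10 (loc_1..loc_9
    span the binding core, loc_0/loc_10 the flanks). Every column sums to 1.
    """
    if not candidates:
        raise ValueError("cannot build a PFM from zero candidates")
    counts = np.zeros((len(AMINO_ACIDS), 11), dtype=float)
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for c in candidates:
        for j, aa in enumerate(c.window11):
            counts[index[aa], j] += 1
    freqs = counts / counts.sum(axis=0, keepdims=True)
    pfm = pd.DataFrame(freqs, index=list(AMINO_ACIDS), columns=PFM_COLUMNS)
    pfm.attrs["n_sequences"] = len(candidates)
    return pfm


def group_logos_by_start(
    candidates: Sequence[CoreCandidate],
) -> dict[str, pd.DataFrame]:
    """Partition binder candidates by the first core residue (loc_1) and build
    one PFM per group.

    Groups cover the input exactly once; the weighted average of the group
    matrices reproduces the global PFM.
    """
    groups: dict[str, list[CoreCandidate]] = defaultdict(list)
    for c in candidates:
        groups[c.core9[0]].append(c)
    return {
        start: position_frequency_matrix(members)
        for start, members in sorted(groups.items())
    }


def prioritize(
    ligands: Sequence[LigandWindow],
    binder_calls: Sequence[BinderCall],
    candidates: Sequence[CoreCandidate],
    taxonomy: Sequence[TaxonAssignment],
    cohort_ids: Iterable[str] = (),
    flagged_species: Iterable[str] = (),
    canonical_motif_id: str | None = None,
) -> pd.DataFrame:
    """Rank ligands by the four candidate-selection criteria.

    1. ``has_canonical_motif`` — the ligand carries the full (un-relaxed)
       footprint motif; relaxed variants do not qualify.
    2. ``in_metagenome_cohort`` — the ligand id or exact sequence appears in
       the user-supplied set of ids/sequences detected in the study cohort.
    3. ``species_flagged`` — a source genome's species (the ``s__`` rank) is
       in the user-supplied disease-associated species set.
    4. ``noncanonical_start`` — a binder core of the ligand starts with F or
       L, the most enriched noncanonical starts among predicted binders.

    Output is sorted by the number of satisfied criteria (descending), ties
    by ligand id. Empty cohort/species sets simply leave those criteria false.
    """
    cohort = set(cohort_ids)
    species_set = set(flagged_species)
    if not cohort:
        logger.warning("prioritize: empty cohort set; criterion 2 all false")
    if not species_set:
        logger.warning("prioritize: empty species set; criterion 3 all false")

    if canonical_motif_id is None:
        # The canonical motif is the one with the most required positions.
        all_motifs = {lig.motif_id for lig in ligands} | {
            m for lig in ligands for (_, _, m, _) in lig.sources
        }
        canonical_motif_id = max(
            all_motifs, key=lambda mid: sum(c != "." for c in mid), default=""
        )

    species_of: dict[str, str] = {}
    for t in taxonomy:
        for token in t.lineage.split(";"):
            token = token.strip()
            if token.startswith("s__"):
                species_of[t.genome_id] = token[3:].strip()

    binder_ids = {b.candidate_id for b in binder_calls if b.is_binder}
    binder_cores_by_ligand: dict[str, list[str]] = defaultdict(list)
    for c in candidates:
        if c.candidate_id in binder_ids:
            binder_cores_by_ligand[c.ligand_ref].append(c.core9)

    rows = []
    for lig in ligands:
        motif_ids = {lig.motif_id} | {m for (_, _, m, _) in lig.sources}
        has_canonical = canonical_motif_id in motif_ids
        in_cohort = lig.ligand_id in cohort or lig.sequence in cohort
        genomes = {lig.genome_id} | {g for (_, _, _, g) in lig.sources}
        flagged = any(species_of.get(g, "") in species_set for g in genomes if g)
        noncanonical = any(
            core[0] in NONCANONICAL_STARTS
            for core in binder_cores_by_ligand.get(lig.ligand_id, [])
        )
        n_criteria = sum((has_canonical, in_cohort, flagged, noncanonical))
        rows.append(
            (lig.ligand_id, lig.sequence, has_canonical, in_cohort, flagged,
             noncanonical, n_criteria)
        )
    df = pd.DataFrame(
        rows,
        columns=["ligand_id", "sequence", "has_canonical_motif",
                 "in_metagenome_cohort", "species_flagged",
                 "noncanonical_start", "n_criteria"],
    )
    return df.sort_values(
        ["n_criteria", "ligand_id"], ascending=[False, True]
    ).reset_index(drop=True)


def plot_logo(pfm: pd.DataFrame, ax=None, title: str = ""):
    """Draw a simple frequency logo from a PFM (letters stacked by frequency).

    Returns the matplotlib Axes. Requires matplotlib; intended for quick
    inspection, the PFM TSV is the analysis contract.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * len(pfm.columns), 2.5))
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    cmap = {aa: c for aa, c in zip(
        AMINO_ACIDS, plt.cm.tab20(np.linspace(0, 1, len(AMINO_ACIDS)))
    )}
    for j, col in enumerate(pfm.columns):
        y = 0.0
        for aa in pfm[col].sort_values().index:
            f = float(pfm.at[aa, col])
            if f <= 0.005:
                continue
            tp = TextPath((0, 0), aa, size=1.0, prop=fp)
            bb = tp.get_extents()
            trans = (
                Affine2D()
                .scale(0.9 / bb.width, f / bb.height)
                .translate(j - 0.45 - bb.x0 * 0.9 / bb.width,
                           y - bb.y0 * f / bb.height)
            )
            ax.add_patch(PathPatch(tp.transformed(trans),
                                   facecolor=cmap[aa], edgecolor="none"))
            y += f
    ax.set_xlim(-0.6, len(pfm.columns) - 0.4)
    ax.set_ylim(0, 1.02)
    ax.set_xticks(range(len(pfm.columns)))
    ax.set_xticklabels(pfm.columns, rotation=45, fontsize=7)
    ax.set_ylabel("frequency")
    if title:
        ax.set_title(title, fontsize=9)
    return ax
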