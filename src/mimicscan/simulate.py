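"""Synthetic inputs with known ground truth for every pipeline stage.

Generates background proteomes with controlled residue frequencies and
GTDB-style taxonomy across phyla, plants footprint-motif-bearing 21-mers at
recorded loci, and emits structure-prediction confidence tables whose binder
labels straddle the triage thresholds by construction. Because every planted
window and every label is recorded, the screen can be validated end-to-end
(planted-recovery recall, exact binder recovery) without any external corpus.

Determinism: all draws come from ``numpy.random.default_rng(seed)``; a fixed
seed reproduces byte-identical FASTA/TSV outputs on any platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from mimicscan.io import (
    AMINO_ACIDS,
    MHC_TEMPLATES,
    TCR_TEMPLATES,
    ConfidenceRecord,
    ProteinRecord,
    TaxonAssignment,
    TcrDockRecord,
)
from mimicscan.motifs import (
    ANCHOR_INDEX,
    WINDOW_LENGTH,
    CoreCandidate,
    FootprintMotif,
    scan_motifs,
)

logger = logging.getLogger("mimicscan")

#: Default phylum mix, loosely modelled on a human gut genome catalogue.
DEFAULT_PHYLUM_WEIGHTS = {
    "Bacillota": 0.40,
    "Bacteroidota": 0.28,
    "Actinomycetota": 0.14,
    "Pseudomonadota": 0.10,
    "Verrucomicrobiota": 0.08,
}


@dataclass
class PlantedWindow:
    genome_id: str
    protein_id: str
    start: int
    window: str
    motif_id: str


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside generated data."""

    seed: int
    planted_windows: list[PlantedWindow] = field(default_factory=list)
    binder_labels: dict[str, bool] = field(default_factory=dict)
    best_run_labels: dict[tuple[str, str], int] = field(default_factory=dict)
    modeled_labels: dict[str, bool] = field(default_factory=dict)

    @property
    def planted_sequences(self) -> set[str]:
        return {p.window for p in self.planted_windows}


def _validate_freqs(residue_freqs: Sequence[float] | None) -> np.ndarray:
    if residue_freqs is None:
        return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    freqs = np.asarray(residue_freqs, dtype=float)
    if freqs.shape != (len(AMINO_ACIDS),) or (freqs < 0).any() or not np.isclose(
        freqs.sum(), 1.0, atol=1e-9
    ):
        raise ValueError(
            f"residue_freqs must be {len(AMINO_ACIDS)} non-negative values summing to 1"
        )
    return freqs


def generate_proteome(
    n_genomes: int = 100,
    phylum_spec: Mapping[str, int] | None = None,
    proteins_per_genome: int = 20,
    length_dist: tuple[float, float] = (300.0, 60.0),
    residue_freqs: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[TaxonAssignment], SyntheticTruth]:
    """Generate a background proteome with GTDB-style taxonomy.

    ``phylum_spec`` maps phylum name to genome count; when omitted,
    ``n_genomes`` genomes are split across the default gut-like phylum mix.
    Protein lengths are normal(mean, sd) clipped at 50 residues; residues are
    i.i.d. draws from ``residue_freqs`` (uniform by default). Protein ids are
    ``{genome_id}|p{j}`` so the source genome travels inside the FASTA header.
    """
    if proteins_per_genome < 1:
        raise ValueError("proteins_per_genome must be >= 1")
    freqs = _validate_freqs(residue_freqs)
    rng = np.random.default_rng(seed)
    if phylum_spec is None:
        if n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        # Largest-remainder apportionment of n_genomes over the default mix.
        names = list(DEFAULT_PHYLUM_WEIGHTS)
        raw = np.array(list(DEFAULT_PHYLUM_WEIGHTS.values())) * n_genomes
        counts = np.floor(raw).astype(int)
        for i in np.argsort(-(raw - counts))[: n_genomes - counts.sum()]:
            counts[i] += 1
        phylum_spec = {
            ph: int(c) for ph, c in zip(names, counts) if c > 0
        }
    if any(c < 1 for c in phylum_spec.values()):
        raise ValueError("phylum genome counts must be >= 1")

    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    mean_len, sd_len = length_dist
    proteins: list[ProteinRecord] = []
    taxonomy: list[TaxonAssignment] = []
    g_index = 0
    for phylum, count in phylum_spec.items():
        for k in range(count):
            genome_id = f"g{g_index:05d}"
            g_index += 1
            lineage = (
                f"d__Bacteria;p__{phylum};c__;o__;f__;"
                f"g__{phylum}_gen;s__{phylum} sp{k:04d}"
            )
            taxonomy.append(TaxonAssignment.from_lineage(genome_id, lineage))
            lengths = np.clip(
                rng.normal(mean_len, sd_len, proteins_per_genome), 50, None
            ).astype(int)
            for j, L in enumerate(lengths):
                seq_codes = rng.choice(alphabet, size=int(L), p=freqs)
                proteins.append(
                    ProteinRecord(
                        id=f"{genome_id}|p{j:04d}",
                        sequence=seq_codes.tobytes().decode(),
                        source_genome=genome_id,
                    )
                )
    return proteins, taxonomy, SyntheticTruth(seed=seed)


def _draw_window(
    motif: FootprintMotif,
    motifs: Sequence[FootprintMotif],
    freqs: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> str:
    """A 21-mer carrying ``motif`` at the anchor index and no stray matches.

    Wildcard positions are drawn from the residue frequencies; the draw is
    rejected until scanning the window with the full motif set finds matches
    only at the anchor offset (so planted windows never contain accidental
    secondary sites).
    """
    aa = list(AMINO_ACIDS)
    for _ in range(max_tries):
        chars = list(rng.choice(aa, size=WINDOW_LENGTH, p=freqs))
        for off, res in motif.required.items():
            chars[ANCHOR_INDEX + off] = res
        window = "".join(chars)
        if all(m.start == ANCHOR_INDEX for m in scan_motifs(window, motifs)):
            return window
    raise RuntimeError("could not draw a clean planted window")


def plant_mimics(
    proteins: Sequence[ProteinRecord],
    motifs: Sequence[FootprintMotif],
    n_plants: int,
    seed: int = 0,
    residue_freqs: Sequence[float] | None = None,
    exact_peptides: Sequence[tuple[str, str]] = (),
    truth: SyntheticTruth | None = None,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Overwrite 21-residue stretches of randomly chosen proteins with
    motif-bearing windows; record the exact loci in the truth object.

    ``n_plants`` counts the randomly drawn windows; ``exact_peptides`` are
    additional (motif_id, 21-mer) pairs planted verbatim (e.g. the MOG and P3
    peptides). Each plant goes into a distinct protein of length >= 21, so
    coordinates and protein lengths are unchanged (overwrite, not insert).
    """
    freqs = _validate_freqs(residue_freqs)
    rng = np.random.default_rng(seed)
    truth = truth or SyntheticTruth(seed=seed)
    eligible = [i for i, p in enumerate(proteins) if len(p) >= WINDOW_LENGTH]
    total = n_plants + len(exact_peptides)
    if total > len(eligible):
        raise ValueError(
            f"cannot plant {total} windows into {len(eligible)} eligible proteins"
        )
    hosts = rng.choice(len(eligible), size=total, replace=False)
    out = list(proteins)
    plants: list[tuple[str, str]] = list(exact_peptides)
    for k in range(n_plants):
        motif = motifs[int(rng.integers(len(motifs)))]
        plants.append((motif.motif_id, _draw_window(motif, motifs, freqs, rng)))
    for host_idx, (motif_id, window) in zip(hosts, plants):
        p = out[eligible[host_idx]]
        start = int(rng.integers(0, len(p) - WINDOW_LENGTH + 1))
        seq = p.sequence[:start] + window + p.sequence[start + WINDOW_LENGTH:]
        out[eligible[host_idx]] = ProteinRecord(p.id, seq, p.source_genome)
        truth.planted_windows.append(
            PlantedWindow(p.source_genome, p.id, start, window, motif_id)
        )
    return out, truth


def generate_score_tables(
    candidates: Sequence[CoreCandidate],
    binder_fraction: float = 0.3,
    seed: int = 0,
    nonconfident_fraction: float = 0.0,
    truth: SyntheticTruth | None = None,
) -> tuple[list[ConfidenceRecord], list[TcrDockRecord], SyntheticTruth]:
    """Confidence tables whose labels straddle the triage thresholds.

    Designated binders draw pLDDT ~ U(92, 98) and inter-PAE ~ U(2.0, 4.0);
    non-binders fail at least one arm (pLDDT ~ U(60, 88) and/or PAE ~
    U(4.5, 12)), so no value sits within 0.5 pLDDT / 0.1 PAE of a threshold.
    Binders additionally get 3 TCR docking runs for each of the 4 templates
    with a designated minimum-PAE run; with probability
    ``nonconfident_fraction`` a binder is made non-confident on one template
    (chosen run pLDDT ~ U(50, 68)), which breaks its all-template modelling.
    """
    if not 0.0 <= binder_fraction <= 1.0:
        raise ValueError("binder_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = truth or SyntheticTruth(seed=seed)
    if not candidates:
        return [], [], truth
    n = len(candidates)
    n_binders = int(round(binder_fraction * n))
    binder_idx = set(rng.choice(n, size=n_binders, replace=False).tolist())

    mhc_records: list[ConfidenceRecord] = []
    tcr_records: list[TcrDockRecord] = []
    for i, cand in enumerate(candidates):
        is_binder = i in binder_idx
        truth.binder_labels[cand.candidate_id] = is_binder
        template = MHC_TEMPLATES[int(rng.integers(len(MHC_TEMPLATES)))]
        if is_binder:
            plddt = rng.uniform(92.0, 98.0)
            pae = rng.uniform(2.0, 4.0)
        else:
            mode = int(rng.integers(3))
            plddt = rng.uniform(60.0, 88.0) if mode in (0, 2) else rng.uniform(92.0, 98.0)
            pae = rng.uniform(4.5, 12.0) if mode in (1, 2) else rng.uniform(2.0, 4.0)
        mhc_records.append(
            ConfidenceRecord(cand.candidate_id, template, round(plddt, 3),
                             round(pae, 3))
        )
        if not is_binder:
            continue
        unmodeled = rng.uniform() < nonconfident_fraction
        truth.modeled_labels[cand.candidate_id] = not unmodeled
        weak_template = (
            TCR_TEMPLATES[int(rng.integers(len(TCR_TEMPLATES)))] if unmodeled else None
        )
        for tmpl in TCR_TEMPLATES:
            best_run = int(rng.integers(1, 4))
            truth.best_run_labels[(cand.candidate_id, tmpl)] = best_run
            paes = np.sort(rng.uniform(4.0, 12.0, size=3))
            paes[1:] += 0.25  # keep the designated minimum strictly lowest
            other = [paes[1], paes[2]]
            for run in (1, 2, 3):
                if run == best_run:
                    run_pae = paes[0]
                else:
                    run_pae = other.pop(0)
                run_plddt = (
                    rng.uniform(50.0, 68.0)
                    if (tmpl == weak_template and run == best_run)
                    else rng.uniform(75.0, 95.0)
                )
                tcr_records.append(
                    TcrDockRecord(cand.candidate_id, tmpl, run,
                                  round(float(run_pae), 3),
                                  round(float(run_plddt), 3))
                )
    return mhc_records, tcr_records, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Planted-window truth as TSV (one row per planted 21-mer)."""
    import pandas as pd

    pd.DataFrame(
        [(p.genome_id, p.protein_id, p.start, p.window, p.motif_id)
         for p in truth.planted_windows],
        columns=["genome_id", "protein_id", "start", "window", "motif_id"],
    ).to_csv(path, sep="\t", index=False)


# Peptides planted verbatim in the packaged example fixture: the mouse MOG
# 35-55 epitope itself and the validated A. muciniphila mimic P3.
FIXTURE_MOG = "MEVGWYRSPFSRVVHLYRNGK"
FIXTURE_P3 = "TTLSFYRPPFLRVRRPFYIIF"


def make_fixture(outdir: str | Path, seed: int = 7) -> SyntheticTruth:
    """Build the tiny documentation/smoke-test fixture.

    Three genomes (one per phylum, the Verrucomicrobiota one relabelled as
    Akkermansia muciniphila), 30 proteins, five planted mimics: MOG 35-55 and
    P3 verbatim (P3 into the A. muciniphila genome) plus three random
    motif-bearing windows. Score tables are generated for the cores the
    filter stages enumerate, and a ready-to-run YAML config is written.
    """
    from mimicscan import io as _io
    from mimicscan import motifs as _motifs
    from mimicscan.analog import mouse_mog35_55

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    epitope = mouse_mog35_55()
    motif_set = _motifs.build_motifs(epitope)
    full_id = motif_set[0].motif_id

    proteins, taxonomy, truth = generate_proteome(
        phylum_spec={"Bacillota": 1, "Bacteroidota": 1, "Verrucomicrobiota": 1},
        proteins_per_genome=10,
        length_dist=(150.0, 30.0),
        seed=seed,
    )
    akk = taxonomy[-1]
    taxonomy[-1] = TaxonAssignment.from_lineage(
        akk.genome_id,
        "d__Bacteria;p__Verrucomicrobiota;c__Verrucomicrobiae;"
        "o__Verrucomicrobiales;f__Akkermansiaceae;g__Akkermansia;"
        "s__Akkermansia muciniphila",
    )
    rng = np.random.default_rng(seed + 1)

    def overwrite(protein_idx: int, window: str) -> None:
        p = proteins[protein_idx]
        start = int(rng.integers(0, len(p) - WINDOW_LENGTH + 1))
        seq = p.sequence[:start] + window + p.sequence[start + WINDOW_LENGTH:]
        proteins[protein_idx] = ProteinRecord(p.id, seq, p.source_genome)
        truth.planted_windows.append(
            PlantedWindow(p.source_genome, p.id, start, window, full_id)
        )

    overwrite(0, FIXTURE_MOG)                 # first Bacillota protein
    akk_first = next(
        i for i, p in enumerate(proteins) if p.source_genome == akk.genome_id
    )
    overwrite(akk_first, FIXTURE_P3)          # into A. muciniphila
    proteins_out, truth = plant_mimics(
        [p for i, p in enumerate(proteins) if i not in (0, akk_first)],
        motif_set, n_plants=3, seed=seed + 2, truth=truth,
    )
    proteins = sorted(
        proteins_out + [proteins[0], proteins[akk_first]], key=lambda p: p.id
    )

    _io.write_fasta(proteins, outdir / "proteins.fasta")
    _io.write_taxonomy_table(taxonomy, outdir / "taxonomy.tsv")
    write_truth(truth, outdir / "truth_windows.tsv")

    by_id = {p.id: p for p in proteins}
    matches = _motifs.scan_proteins(proteins, motif_set)
    windows = [_motifs.truncate_window(by_id[m.sequence_id], m) for m in matches]
    ligands = _motifs.dedup_ligands(windows)
    candidates = [c for lig in ligands for c in _motifs.enumerate_cores(lig)]
    mhc_records, tcr_records, truth = generate_score_tables(
        candidates, binder_fraction=0.4, seed=seed + 3, truth=truth
    )
    _io.write_score_tables(
        mhc_records, tcr_records,
        outdir / "mhc_scores.tsv", outdir / "tcr_scores.tsv",
    )

    config = f"""\
epitope:
  builtin: mouse_mog35_55
inputs:
  proteins: proteins.fasta
  taxonomy: taxonomy.tsv
  mhc_scores: mhc_scores.tsv
  tcr_scores: tcr_scores.tsv
search:
  bypass: true
thresholds:
  plddt_min: 90.0
  inter_pae_max: 4.34
  confident_plddt_min: 70.0
profiling:
  min_genomes: 10
prioritize:
  cohort_ids: [{FIXTURE_P3}]
  flagged_species: [Akkermansia muciniphila]
output:
  dir: out
seed: {seed}
"""
    (outdir / "config.yaml").write_text(config)
    return truth
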