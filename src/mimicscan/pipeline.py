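"""End-to-end orchestration: analog search -> motif filter -> truncation ->
dedup -> core enumeration -> binder triage -> profiling -> prioritization.

Every stage materialises a TSV in the output directory so the funnel can be
inspected or re-run stage by stage; a deterministic ``manifest.json`` records
the config snapshot, seed and per-stage counts. Wall-clock information goes to
the log, never into the manifest or the TSVs, so re-running an identical
config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from mimicscan import analog, io, motifs, profiling, simulate, triage

logger = logging.getLogger("mimicscan")


@dataclass
class RunConfig:
    """Run configuration, loadable from YAML (see `load_config`)."""

    epitope: analog.EpitopeQuery
    outdir: Path
    proteins: Path | None = None
    taxonomy: Path | None = None
    mhc_scores: Path | None = None
    tcr_scores: Path | None = None
    alignment_hits: Path | None = None
    bypass_alignment: bool = False
    evalue_threshold: float = 0.001
    alignment_params: analog.AlignmentParams = field(
        default_factory=analog.AlignmentParams
    )
    thresholds: triage.TriageThresholds = field(
        default_factory=triage.TriageThresholds
    )
    min_genomes: int = profiling.DEFAULT_MIN_GENOMES
    cohort_ids: list[str] = field(default_factory=list)
    flagged_species: list[str] = field(default_factory=list)
    synthetic: dict[str, Any] | None = None
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration.

    Sections: ``epitope`` (either ``builtin: mouse_mog35_55`` or explicit
    name/sequence/footprint/mhc_anchor_offset), ``inputs`` (proteins,
    taxonomy, mhc_scores, tcr_scores, alignment_hits), ``search`` (bypass,
    evalue, matrix, gap_open, gap_extend, K, lam), ``thresholds``,
    ``profiling`` (min_genomes), ``prioritize`` (cohort_ids,
    flagged_species), ``synthetic``, ``output`` (dir), ``seed``.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent

    epi_cfg = raw.get("epitope") or {"builtin": "mouse_mog35_55"}
    if "builtin" in epi_cfg:
        name = epi_cfg["builtin"]
        if name not in analog.BUILTIN_EPITOPES:
            raise ValueError(
                f"unknown builtin epitope {name!r}; "
                f"available: {sorted(analog.BUILTIN_EPITOPES)}"
            )
        epitope = analog.BUILTIN_EPITOPES[name]()
    else:
        epitope = analog.EpitopeQuery(
            name=epi_cfg["name"],
            sequence=epi_cfg["sequence"].upper(),
            footprint={int(k): v for k, v in epi_cfg["footprint"].items()},
            mhc_anchor_offset=int(epi_cfg["mhc_anchor_offset"]),
        )

    inputs = raw.get("inputs") or {}

    def _p(key: str) -> Path | None:
        v = inputs.get(key)
        if v is None:
            return None
        p = Path(v)
        return p if p.is_absolute() else base / p

    search = raw.get("search") or {}
    thr = raw.get("thresholds") or {}
    prof = raw.get("profiling") or {}
    prio = raw.get("prioritize") or {}
    out = raw.get("output") or {}
    outdir = Path(out.get("dir", "mimicscan_out"))
    if not outdir.is_absolute():
        outdir = base / outdir

    return RunConfig(
        epitope=epitope,
        outdir=outdir,
        proteins=_p("proteins"),
        taxonomy=_p("taxonomy"),
        mhc_scores=_p("mhc_scores"),
        tcr_scores=_p("tcr_scores"),
        alignment_hits=_p("alignment_hits"),
        bypass_alignment=bool(search.get("bypass", False)),
        evalue_threshold=float(search.get("evalue", 0.001)),
        alignment_params=analog.AlignmentParams(
            matrix=search.get("matrix", "BLOSUM62"),
            gap_open=int(search.get("gap_open", 11)),
            gap_extend=int(search.get("gap_extend", 1)),
            K=float(search.get("K", analog.DEFAULT_K)),
            lam=float(search.get("lam", analog.DEFAULT_LAMBDA)),
        ),
        thresholds=triage.TriageThresholds(
            plddt_min=float(thr.get("plddt_min", 90.0)),
            inter_pae_max=float(thr.get("inter_pae_max", 4.34)),
            confident_plddt_min=float(thr.get("confident_plddt_min", 70.0)),
        ),
        min_genomes=int(prof.get("min_genomes", profiling.DEFAULT_MIN_GENOMES)),
        cohort_ids=list(prio.get("cohort_ids", [])),
        flagged_species=list(prio.get("flagged_species", [])),
        synthetic=raw.get("synthetic"),
        seed=int(raw.get("seed", 0)),
    )


def _config_snapshot(config: RunConfig) -> dict[str, Any]:
    snap = {
        "epitope": {
            "name": config.epitope.name,
            "sequence": config.epitope.sequence,
            "footprint": {str(k): v for k, v in config.epitope.footprint.items()},
            "mhc_anchor_offset": config.epitope.mhc_anchor_offset,
        },
        "bypass_alignment": config.bypass_alignment,
        "evalue_threshold": config.evalue_threshold,
        "alignment_params": asdict(config.alignment_params),
        "thresholds": asdict(config.thresholds),
        "min_genomes": config.min_genomes,
        "cohort_ids": sorted(config.cohort_ids),
        "flagged_species": sorted(config.flagged_species),
        "synthetic": config.synthetic,
        "seed": config.seed,
    }
    for key in ("proteins", "taxonomy", "mhc_scores", "tcr_scores",
                "alignment_hits"):
        v = getattr(config, key)
        snap[key] = str(v) if v is not None else None
    return snap


def _synthesize_inputs(config: RunConfig, outdir: Path):
    """Generate proteome + taxonomy (+ plants) per the synthetic config section."""
    spec = dict(config.synthetic or {})
    motif_set = motifs.build_motifs(config.epitope)
    proteins, taxonomy, truth = simulate.generate_proteome(
        n_genomes=int(spec.get("n_genomes", 100)),
        phylum_spec=spec.get("phylum_spec"),
        proteins_per_genome=int(spec.get("proteins_per_genome", 20)),
        length_dist=tuple(spec.get("length_dist", (300.0, 60.0))),
        residue_freqs=spec.get("residue_freqs"),
        seed=config.seed,
    )
    exact = [tuple(x) for x in spec.get("exact_peptides", [])]
    proteins, truth = simulate.plant_mimics(
        proteins,
        motif_set,
        n_plants=int(spec.get("n_plants", 50)),
        seed=config.seed + 1,
        residue_freqs=spec.get("residue_freqs"),
        exact_peptides=exact,
        truth=truth,
    )
    io.write_fasta(proteins, outdir / "inputs" / "proteins.fasta")
    io.write_taxonomy_table(taxonomy, outdir / "inputs" / "taxonomy.tsv")
    simulate.write_truth(truth, outdir / "inputs" / "truth_windows.tsv")
    return proteins, taxonomy, truth, spec


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full screen; returns the run manifest (also written as
    ``manifest.json`` in the output directory)."""
    outdir = Path(config.outdir)
    (outdir / "inputs").mkdir(parents=True, exist_ok=True)
    _setup_file_log(outdir)

    truth: simulate.SyntheticTruth | None = None
    synth_spec: dict[str, Any] = {}
    if config.synthetic is not None:
        proteins, taxonomy, truth, synth_spec = _synthesize_inputs(config, outdir)
    else:
        if config.proteins is None or config.taxonomy is None:
            raise ValueError(
                "config must provide inputs.proteins and inputs.taxonomy, or a "
                "synthetic section"
            )
        proteins = io.read_fasta(config.proteins)
        taxonomy = io.read_taxonomy_table(config.taxonomy)

    # Stage 1: analog search (optional bypass).
    if config.bypass_alignment:
        subjects = proteins
        n_analog_hits = len(proteins)
        logger.info("alignment bypassed: scanning all %d proteins", len(proteins))
    elif config.alignment_hits is not None:
        rows = io.ingest_alignment_hits(config.alignment_hits,
                                        config.evalue_threshold)
        hit_ids = {r.subject_id for r in rows}
        subjects = [p for p in proteins if p.id in hit_ids]
        n_analog_hits = len(rows)
    else:
        hits = analog.search_analogs(
            config.epitope, proteins, config.evalue_threshold,
            config.alignment_params,
        )
        io.write_alignment_hits(
            analog.hits_to_rows(config.epitope, hits),
            outdir / "analog_hits.tsv",
        )
        hit_ids = {h.subject_id for h in hits}
        subjects = [p for p in proteins if p.id in hit_ids]
        n_analog_hits = len(hits)

    # Stage 2: footprint motif scan.
    motif_set = motifs.build_motifs(config.epitope)
    matches = motifs.scan_proteins(subjects, motif_set)
    pd.DataFrame(
        [(m.sequence_id, m.genome_id, m.motif_id, m.start, m.matched_9mer)
         for m in matches],
        columns=["sequence_id", "genome_id", "motif_id", "start", "matched_9mer"],
    ).to_csv(outdir / "motif_matches.tsv", sep="\t", index=False)

    # Stage 3: truncation and global dedup.
    by_id = {p.id: p for p in subjects}
    windows = [motifs.truncate_window(by_id[m.sequence_id], m) for m in matches]
    ligands = motifs.dedup_ligands(windows)
    pd.DataFrame(
        [(l.ligand_id, l.sequence, l.parent_id, l.parent_start, l.motif_id,
          l.anchor_index, l.genome_id, l.multiplicity) for l in ligands],
        columns=["ligand_id", "sequence", "parent_id", "parent_start",
                 "motif_id", "anchor_index", "genome_id", "multiplicity"],
    ).to_csv(outdir / "ligands.tsv", sep="\t", index=False)

    # Stage 4: core enumeration.
    candidates = [c for lig in ligands for c in motifs.enumerate_cores(lig)]
    pd.DataFrame(
        [(c.candidate_id, c.window11, c.core9, c.ligand_ref, c.start_in_ligand)
         for c in candidates],
        columns=["candidate_id", "window11", "core9", "ligand_ref",
                 "start_in_ligand"],
    ).to_csv(outdir / "core_candidates.tsv", sep="\t", index=False)

    # Stage 5: confidence scores (read or synthesize) and binder triage.
    if config.synthetic is not None:
        mhc_records, tcr_records, truth = simulate.generate_score_tables(
            candidates,
            binder_fraction=float(synth_spec.get("binder_fraction", 0.3)),
            seed=config.seed + 2,
            nonconfident_fraction=float(
                synth_spec.get("nonconfident_fraction", 0.0)
            ),
            truth=truth,
        )
        io.write_score_tables(
            mhc_records, tcr_records,
            outdir / "inputs" / "mhc_scores.tsv",
            outdir / "inputs" / "tcr_scores.tsv",
        )
    elif config.mhc_scores is not None and config.tcr_scores is not None:
        mhc_records, tcr_records = io.read_score_tables(
            config.mhc_scores, config.tcr_scores
        )
    else:
        logger.warning("no score tables: triage stage will see zero records")
        mhc_records, tcr_records = [], []

    known = {c.candidate_id for c in candidates}
    unmatched = [r for r in mhc_records if r.candidate_id not in known]
    if unmatched:
        logger.warning(
            "%d confidence records do not match any candidate", len(unmatched)
        )
    calls = triage.classify_binders(
        [r for r in mhc_records if r.candidate_id in known], config.thresholds
    )
    pd.DataFrame(
        [(b.candidate_id, b.peptide_plddt, b.inter_pae, b.is_binder)
         for b in calls],
        columns=["candidate_id", "peptide_plddt", "inter_pae", "is_binder"],
    ).to_csv(outdir / "binder_calls.tsv", sep="\t", index=False)

    best = triage.select_best_models(
        [r for r in tcr_records if r.candidate_id in known], config.thresholds
    )
    pd.DataFrame(
        [(m.candidate_id, m.tcr_template, m.chosen_run, m.pae_tcr_pmhc,
          m.confident) for m in best],
        columns=["candidate_id", "tcr_template", "chosen_run", "pae_tcr_pmhc",
                 "confident"],
    ).to_csv(outdir / "best_models.tsv", sep="\t", index=False)
    frac = triage.modeled_fraction(calls, best) if calls else float("nan")

    # Stage 6: profiling.
    profile = profiling.phylum_profile(matches, taxonomy, config.min_genomes)
    profile.to_csv(outdir / "phylum_profile.tsv", sep="\t", index=False)

    binder_ids = {b.candidate_id for b in calls if b.is_binder}
    binder_candidates = [c for c in candidates if c.candidate_id in binder_ids]
    if binder_candidates:
        pfm = profiling.position_frequency_matrix(binder_candidates)
        pfm.to_csv(outdir / "pfm.tsv", sep="\t")
        groups = profiling.group_logos_by_start(binder_candidates)
        rows = []
        for start, gpfm in groups.items():
            for aa in gpfm.index:
                for col in gpfm.columns:
                    rows.append((start, gpfm.attrs["n_sequences"], aa, col,
                                 gpfm.at[aa, col]))
        pd.DataFrame(
            rows, columns=["start_residue", "n_sequences", "residue",
                           "position", "frequency"],
        ).to_csv(outdir / "pfm_groups.tsv", sep="\t", index=False)
    else:
        logger.warning("zero binders: PFM and logo outputs skipped")

    # Stage 7: prioritization.
    ranking = profiling.prioritize(
        ligands, calls, candidates, taxonomy,
        cohort_ids=config.cohort_ids,
        flagged_species=config.flagged_species,
        canonical_motif_id=motif_set[0].motif_id,
    )
    ranking.to_csv(outdir / "prioritization.tsv", sep="\t", index=False)

    binder_ligands = {c.ligand_ref for c in candidates
                      if c.candidate_id in binder_ids}
    manifest = {
        "config": _config_snapshot(config),
        "seed": config.seed,
        "counts": {
            "proteins": len(proteins),
            "analog_hits": n_analog_hits,
            "motif_matches": len(matches),
            "matched_sequences": len({m.sequence_id for m in matches}),
            "ligand_windows": len(windows),
            "nonredundant_ligands": len(ligands),
            "core_candidates": len(candidates),
            "scored_candidates": len(calls),
            "binders": len(binder_ids),
            "binder_ligands": len(binder_ligands),
        },
        "modeled_fraction": None if frac != frac else round(frac, 6),
        "outputs": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
            and p.name != "run.log"
        ),
    }
    _check_funnel(manifest["counts"])
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _check_funnel(counts: Mapping[str, int]) -> None:
    """Filter stages can only shrink the candidate pool."""
    assert counts["matched_sequences"] <= max(counts["analog_hits"],
                                              counts["proteins"])
    assert counts["nonredundant_ligands"] <= counts["ligand_windows"]
    assert counts["binders"] <= counts["scored_candidates"]
    assert counts["binder_ligands"] <= counts["nonredundant_ligands"]


def _setup_file_log(outdir: Path) -> None:
    # One file handler per output dir; avoid duplicates on repeat runs.
    log_path = outdir / "run.log"
    root = logging.getLogger("mimicscan")
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
            h.close()
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    root.addHandler(handler)
    root.setLevel(logging.INFO)
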