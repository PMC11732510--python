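# mimicscan

Screen microbial protein collections for **molecular mimics of a self-epitope**
at the MHC class II–TCR interface.

Gut bacteria encode peptides that resemble host autoantigens closely enough to
activate autoreactive T cells — a proposed trigger for autoimmune diseases such
as multiple sclerosis. Cross-reactivity does not require overall sequence
similarity: it is driven by a small *TCR-binding footprint*, the handful of
peptide residues the MHC II molecule and the T-cell receptor actually contact,
conserved at fixed spacing ("hotspot mimicry"). `mimicscan` implements this
footprint-based screen end to end for bioinformaticians studying
microbiome–autoimmunity links, using the encephalitogenic myelin epitope
MOG 35‑55 as the built-in reference query.

## The screen

For MOG 35‑55 (`MEVGWYRSPFSRVVHLYRNGK`), Y40 anchors the MHC II p1 pocket and
R41, F44, R46, V47 are the dominant TCR contacts. The footprint compiles into
five degenerate 9-position motifs — the full pattern

```
Y R x x F x R V x
```

plus the four variants that each relax exactly one TCR contact (the MHC anchor
is never relaxed). The pipeline stages:

1. **Analog search** — Smith–Waterman local alignment of the epitope against
   every subject protein (BLOSUM62, affine gaps 11/1), Karlin–Altschul
   e-values with cutoff 0.001. May be bypassed to scan all proteins directly.
2. **Footprint filter** — scan sequences for the five motifs at every offset;
   around each match truncate a ~21-residue ligand window with the anchor at
   index 5 (a fixed-window surrogate for proteolytic antigen processing);
   deduplicate windows globally by exact sequence.
3. **Core enumeration** — chop each ligand into stride-1 11-mers; the central
   9-mer is the putative MHC II binding core (a length-L ligand yields L−10).
4. **Binder triage** — classify each core from structure-prediction
   confidence scalars: binder ⇔ peptide pLDDT ≥ 90 **and** mean inter-chain
   lowest PAE ≤ 4.34. For TCR docking, keep the lowest-PAE model of three
   runs per (candidate, TCR template); pLDDT ≥ 70 marks it confidently
   modelled.
5. **Profiling & prioritization** — per-phylum analog rates normalised by
   genome counts (phyla with < 10 genomes pool into "Others"),
   position-frequency matrices and per-start-residue logos over binder cores,
   and a four-criterion ranking (canonical motif; detected in a metagenome
   cohort; disease-associated source species; noncanonical F/L core start).

A fully seeded synthetic-data module generates proteomes with planted mimics
and threshold-straddling score tables, so every stage is validated against
known ground truth without external downloads.

## Worked example

The repository ships a tiny fixture (3 genomes, 30 proteins, 5 planted
mimics — among them MOG 35‑55 itself and the *Akkermansia muciniphila* mimic
P3 `TTLSFYRPPFLRVRRPFYIIF`):

```sh
mimicscan run-all examples/fixture/config.yaml
```

prints the stage funnel

```
proteins: 30
analog_hits: 30
motif_matches: 17
nonredundant_ligands: 5
core_candidates: 55
binders: 22
modeled_fraction: 1.0
```

30 proteins carry 17 motif occurrences (a full-motif site also satisfies the
relaxed variants) that collapse to the 5 planted 21-mer ligands; these chop
into 55 core candidates of which 22 pass the pLDDT/PAE thresholds, and every
binder is confidently modelled against all four TCR templates. The
prioritization table ranks the P3 ligand first with all four criteria
satisfied:

```
ligand_id   sequence               has_canonical_motif  in_metagenome_cohort  species_flagged  noncanonical_start  n_criteria
lig_00002   TTLSFYRPPFLRVRRPFYIIF  True                 True                  True             True                4
```

Stage tables (`ligands.tsv`, `core_candidates.tsv`, `binder_calls.tsv`,
`phylum_profile.tsv`, `pfm.tsv`, `prioritization.tsv`) and a deterministic
`manifest.json` are written to the configured output directory. The same
stages are available programmatically (`mimicscan.scan_motifs`,
`mimicscan.classify_binder`, …) and as individual subcommands
(`simulate`, `search`, `filter`, `triage`, `profile`).

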