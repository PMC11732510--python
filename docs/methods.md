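# Methods

## Model

`mimicscan` operationalises hotspot molecular mimicry: a microbial peptide is
a candidate mimic of a self-epitope when it conserves the epitope's
MHC-anchor and TCR-contact residues at the same spacing, regardless of
similarity elsewhere. The reference query is MOG 35‑55
(`MEVGWYRSPFSRVVHLYRNGK`, mouse; the human variant has P instead of S at
position 42, outside the footprint, so both compile to identical motifs).
The footprint places the MHC II p1 anchor Y40 at epitope offset 5 and TCR
contacts R41/F44/R46/V47 at offsets 6/9/11/12.

Rebasing to the 9-residue core frame (anchor at 0) gives the full motif
`YR..F.RV.` and four single-relaxation variants (`Y...F.RV.`, `YR....RV.`,
`YR..F..V.`, `YR..F.R..`). The relaxation model assumes the MHC anchor is
indispensable while any single TCR contact may vary; relaxing two or more
contacts is not considered. Matching is exact residue identity — the
ambiguity letter X never satisfies a required position — and degenerate
positions are unconstrained. This is deliberately not a probabilistic PWM:
the screen's premise is that the footprint residues are individually
necessary.

## Pipeline stages and parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| analog search | substitution matrix | BLOSUM62 | standard protein-search default |
| | gap open / extend | 11 / 1 (cost of a length-k gap: 11 + k) | standard protein-search default |
| | Karlin–Altschul K, λ | 0.041, 0.267 | published gapped BLOSUM62 values |
| | e-value cutoff | 0.001, inclusive (≤) | screen's retention threshold; inclusive matches common tool convention |
| footprint filter | window length | 21 residues, anchor at index 5, clamped at termini | both reference 21-mers (MOG 35‑55, P3) place the motif Y at index 5 |
| core enumeration | window / core | 11-mer, central 9-mer, stride 1 | structure predictors for pMHC II consume a 9-mer core plus one flank each side |
| binder triage | pLDDT ≥ | 90 | binder-classification cutoff for the peptide's scalar confidence |
| | inter-chain PAE ≤ | 4.34 | binder-classification cutoff for peptide↔MHC placement error |
| | confident pLDDT ≥ | 70 | confidence bar for a chosen docking model |
| profiling | min genomes per phylum | 10 | smaller phyla (and unclassified contigs) pool into "Others" |

The alignment stage can be bypassed (`search.bypass: true`): the motif filter
is the discriminating stage, and scanning every protein directly is exact.
This is also the configuration under which planted-truth validation is
meaningful, since a planted window that conserves only the five footprint
residues generally scores far below the e-value cutoff against the query —
exactly the peptides the motif stage exists to find.

Confidence scalars are consumed, never produced: `peptide_plddt` is the mean
per-residue pLDDT of the modelled 11-mer, and `inter_pae` the mean over
peptide residues of the lowest PAE against any MHC residue (both matrix
directions). The reducer from a raw PAE matrix to that scalar is provided
(`triage.reduce_inter_pae`) for users holding full matrices, but scalar TSVs
are the contract. The all-templates-confident "modelled fraction" implements
one reasonable reading of modelling success (chosen model of every one of the
four TCR templates confident at pLDDT ≥ 70); other denominators are
conceivable and the quantity should be read as this package defines it.

## Numerical and bookkeeping choices

- **Coordinates** are 0-based half-open everywhere in memory; the 12-column
  alignment dialect's 1-based inclusive coordinates are converted exactly
  once at I/O.
- **Local alignment** is Biopython's `PairwiseAligner` (affine Gotoh, C
  implementation). Scores are exact integers under BLOSUM62; spans come from
  the aligner's deterministic first optimal traceback. Co-optimal alignments
  share the score, which is what the e-value and all downstream decisions
  consume.
- **Tie-breaks**: best-of-3 docking-run selection resolves PAE ties by lowest
  run index; ligand dedup keeps the first window in input order as
  representative and accumulates sources/multiplicity; prioritization sorts
  by criteria count then ligand id. All are deterministic.
- **Degenerate inputs**: an empty proteome or zero binders produce empty
  downstream tables with warnings, not errors; a zero-binder run has an
  undefined modelled fraction (NaN). Ligands shorter than 11 residues yield
  no cores. X-containing 11-mer windows are excluded from core enumeration
  (their cores are uninterpretable under exact-residue matching); in lenient
  FASTA mode non-canonical residues are masked to X, in strict mode they are
  errors.
- **Dedup scope** is global across genomes, keyed on the full ligand window
  string (21-mer identity). Keying on the 11-mer or 9-mer would merge more
  aggressively; the window is the unit the screen reports.
- **Core counting**: a 21-mer yields 11 stride-1 windows (L−10). Duplicate
  11-mers within one ligand collapse.

## Synthetic data: what it emulates, and what it does not

The generator stands in for a genome catalogue plus structure-prediction
outputs. Defaults (chosen once as the validation conditions): 100 genomes
split over a gut-like five-phylum mix, 20 proteins per genome with lengths
normal(300, 60) clipped at 50, i.i.d. **uniform** residue frequencies, 50
planted mimics, binder fraction 0.3. Uniform frequencies make the background
match rate exactly computable — per offset, inclusion–exclusion over the four
relaxed motifs gives 4·(1/20)⁴ − 3·(1/20)⁵ ≈ 2.4×10⁻⁵ — so recovered-minus-
planted ligand counts can be tested against a closed-form Poisson
expectation.

Planting overwrites 21 contiguous residues (never inserts), fixes the motif's
required residues, draws wildcards from the background frequencies, and
rejection-samples until the window contains no motif occurrence other than at
the anchor. Score tables draw binders from pLDDT ~ U(92, 98) × PAE ~
U(2.0, 4.0) and non-binders failing at least one arm (pLDDT U(60, 88), PAE
U(4.5, 12)), leaving ≥ 0.5 pLDDT / ≥ 0.1 PAE margins around the thresholds so
label recovery is float-robust. Each binder gets 3 runs × 4 TCR templates
with a designated strictly-minimal-PAE run.

What the generator does **not** emulate: realistic amino-acid composition and
its correlation structure (real proteomes are far from i.i.d. uniform),
homology between genomes (real "nonredundant" collapses are much larger),
any dependence of confidence scores on the actual peptide sequence, or raw
PAE matrices. Passing the planted-recovery and triage tests therefore
demonstrates the *bookkeeping* of the screen is exact — scanning, windowing,
dedup, thresholds, selection — not that the thresholds themselves are
biologically optimal, which only the upstream structure predictors and
downstream experiments can speak to.

Problem sizes in tests and in the acceptance script (100-genome corpora,
10,000-sequence oracle sweeps, 500 alignment pairs) were chosen to exercise
the properties at comfortable statistical power while keeping a full
validation run in the seconds-to-minutes range on one CPU.

## Known limitations

- The ~21-residue truncation is a fixed-window surrogate for antigen
  processing; no protease-cleavage model is applied.
- One reported alignment hit per subject; multiple strong local matches in
  one protein are represented only by the best (the motif scan still sees the
  whole sequence).
- Phylum profiling counts every motif occurrence (redundant analogs);
  a nonredundant variant is a configuration away but not the default.
- Criterion 2 of prioritization (cohort detection) is membership in a
  user-supplied id/sequence set; the metagenome detection itself is out of
  scope.
- Strain-level attribution of ligands is not attempted.
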