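epitope:
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
  cohort_ids: [TTLSFYRPPFLRVRRPFYIIF]
  flagged_species: [Akkermansia muciniphila]
output:
  dir: out
seed: 7
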