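# Demo: fully synthetic strain with one antisense 3'-UTR unistrand source,
# one silent full-length copy, one dual-strand germline source, and six
# germline reference TEs. Deterministic for the seed.
seed: 1
outdir: results/demo
simulate:
  utr_orientation: antisense
  n_unistrand: 2500
  n_germ_pairs: 400
  n_reference_pairs: 250
  n_mirna: 20000
  dna_coverage: 30.0
  with_embryo: true
params:
  max_mismatches: 2
  min_len: 23
  max_len: 32
  flank_window: 2000
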