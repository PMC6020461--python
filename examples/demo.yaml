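# Demonstration pipeline configuration (all stages on synthetic data).
schema_version: 1
seed: 7
simulation:
  n_genes: 60
calling:
  alpha: 0.05
  min_coverage: 10
  mode: fisher
clustering:
  d: 10
  n_perm: 200
differential:
  enabled: true
  utr5_scale: 3.0
  alpha: 0.05
dna:
  enabled: true
association:
  enabled: true
  n_genes: 1000
  rho_fc: 0.3
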