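# Bundled end-to-end demo: a small but complete synthetic study.
# Identical to the configuration the golden-run test reproduces.
seed: 11
outdir: demo_run
simulate:
  n_chroms: 2
  chrom_len: 300000
  n_genes: 120
  n_tes: 50
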