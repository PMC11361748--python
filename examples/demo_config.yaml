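# Scaled-down synthetic end-to-end run (completes in a few seconds).
out_dir: tarsig_demo
bulk_sim:
  n_genes: 600
  n_per_class: 30
  seed: 7
homolog:
  p_unmapped: 0.2
  p_one_to_many: 0.1
  seed: 8
sc_sim:
  n_kc: 300
  n_myeloid: 150
  n_tc: 150
  n_mel: 150
  n_background_genes: 800
  seed: 9
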