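{
  "out_dir": "scratch/demo_out",
  "seed": 7,
  "dataset_name": "demo-synthetic",
  "simulate": {
    "n_subtypes": 4,
    "samples_per_subtype": 10,
    "blocks_per_subtype": 2,
    "block_size": 5,
    "effect_size": 3.0,
    "within_block_correlation": 0.85,
    "n_noise_genes": 100
  }
}
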