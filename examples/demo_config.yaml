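# Demo pipeline configuration: a small capture-like experiment with one
# replicated donor.  Regenerate the full artifact directory with:
#   forensnp run --config examples/demo_config.yaml --out-dir demo_out
seed: 7
panel:
  n_autosomal: 2000
  n_y: 100
samples:
  n: 6
  sex_ratio: 0.5
  replicates_of: [ind000]
simulate:
  preset: capture_like
calling:
  min_depth: 10
  min_quality: 20.0
match:
  base_error: 0.01
  sample_error_factor: 2.0
  n_select: 2000
  min_snps: 150
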