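# Example pipeline configuration (see cafsig.pipeline.demo_config for the
# schema).  Run with: cafsig run --config examples/run_config.yaml --out my_run
seed: 7
synthetic:
  cohorts:
    n_cohorts: 5
    samples_per_cohort: 60
    n_genes: 150
    n_up: 15
    n_down: 15
    effect_size: 1.5
    batch_sd: 0.5
  spatial:
    n_sections_responder: 4
    n_sections_nonresponder: 4
    n_reference_cells: 15
    cells_per_type: 100
split:
  training: [C01, C02]
  internal: [C03]
  external: [C04, C05]
manifest: reduced      # default (113 combos) | reduced (20) | reduced-mini (6)
min_genes: 5
top_k: 20
k: 10                  # spatial k-distance neighbours
alpha: 0.25            # enrichment rank-weight exponent
meta_or_max_genes: 20
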