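# Complete runnable example: simulate a small nine-region survey and run
# every stage. `cortaxis run --config examples/config.yaml`
seed: 1
output_dir: cortaxis_out
axis: RC
subclass: "L2/3 IT"
method: pearson
sample_mode: per_sample

axes:
  RC: [ACC, DFC, FI, M1C, S1C, MTG, A1C, AnG, V1C]
  TS: [ACC, FI, DFC, AnG, MTG, M1C, S1C, A1C, V1C]

simulate:
  n_regions: 9
  n_donors: 4
  subclasses: ["L2/3 IT", "PVALB", "Astro"]
  genes_per_subclass: 400
  cells_per_group: 60
  frac_trend: 0.05
  trend_slope: 0.3
  nb_dispersion: 0.1
  donor_sd: 0.2
  eregulons:
    n_tfs: 4
    enhancers_per_tf: 3
    genes_per_enhancer: 2
    n_background: 100

gene_filter: {min_count: 10, min_total_count: 15}
peak_filter: {min_count: 5, min_total_count: 15}
gene_thresholds: {min_abs_r: 0.7, max_q: 0.01}
peak_thresholds: {min_abs_r: 0.5, max_q: 0.05}
spatial_params: {radius_um: 200, n_query: 100, grid_size: 1000}

# synthetic receptor-family map: the switching report needs family -> gene
# lists; with simulated gene ids this exercises the machinery only
receptor_families:
  demo-family-1: [G00001, G00002]
  demo-family-2: [G00003, G00004]
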