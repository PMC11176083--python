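# Demo end-to-end run: 2,000 individuals, 50 synthetic genes, 3 driver sites.
#   clonalselect run-all examples/demo_config.yaml --out runs/demo
seed: 7
out_dir: runs/demo
n_genes: 50
gene_length_codons: [120, 400]
splice_sites_per_gene: 0
# each auto driver is a [selection coefficient per year, site mutation rate
# per cell per year] pair placed at the first missense site of the i-th gene
auto_drivers:
  - [0.20, 1.0e-6]
  - [0.15, 2.0e-6]
  - [0.12, 4.0e-6]
sim:
  n_individuals: 2000
  age_low: 40.0
  age_high: 70.0
  ntau: 140000.0
  driver_sites: []
  passenger_rate: 1.0
  passenger_indel_fraction: 0.1
  passenger_subclonality: 1.0
  germline_sites_per_indiv: 2
  depth_median: 45
  depth_dispersion: 20.0
  error_rate: 0.001
  error_sites_per_indiv: 20
  f_min: 0.02
  artifact_rate: 0.3
  cnv_rate: 0.01
  seed: 0
filter: {}
dnds_q_threshold: 0.1
fitness_top_k: 5
fitness_f_min: 0.11
classify_canonical_genes: []
classify_pinned_driverless_count: null
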