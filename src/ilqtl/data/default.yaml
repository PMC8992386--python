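# Default small run configuration: three-chromosome test genome, markers
# every 2.5 Mb, BC2F2 scheme, one planted grain-length QTL.
seed: 1
simulate: true
output_dir: results/run
genome:
  chr1: 30000000
  chr2: 25000000
  chr3: 20000000
markers:
  spacing_bp: 2500000
scheme:
  n_backcrosses: 2
  n_selfs: 2
n_lines: 200
qtls:
  - {chromosome: chr1, position_bp: 15000000, trait: GL, additive: 1.5}
phenotype:
  trait: GL
  baseline: 7.0
  residual_sd: 0.2
  n_replicates: 3
  n_control_replicates: 10
  environment_effects: {E1: 0.0, E2: 0.15}
donor: sim_donor
screen:
  alpha: 1.0e-4
scan:
  p0_mode: empirical_locus
  threshold: 1.0e-3
  window_bp: 2500000
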