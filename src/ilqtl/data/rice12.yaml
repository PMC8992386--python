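# Twelve-chromosome rice-scale configuration (lengths in bp, Mb-rounded).
seed: 1
simulate: true
output_dir: results/rice12
genome:
  chr1: 43000000
  chr2: 36000000
  chr3: 36000000
  chr4: 35000000
  chr5: 30000000
  chr6: 31000000
  chr7: 30000000
  chr8: 28000000
  chr9: 23000000
  chr10: 23000000
  chr11: 29000000
  chr12: 27000000
markers:
  spacing_bp: 2500000
scheme:
  n_backcrosses: 2
  n_selfs: 2
n_lines: 100
qtls:
  - {chromosome: chr3, position_bp: 16730000, trait: GL, additive: 1.5}
phenotype:
  trait: GL
  baseline: 7.0
  residual_sd: 0.2
  n_replicates: 3
  n_control_replicates: 10
  environment_effects: {E1: 0.0, E2: 0.15}
donor: sim_donor
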