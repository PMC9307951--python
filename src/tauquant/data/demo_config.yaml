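# Demo pipeline configuration (synthetic data; ground truth known).
# The mouse-like world: 1N4R-P301S tau peptides, phospho map with sites at
# canonical S202 / T231 / S262; biosensor wells at three seeding levels in
# technical triplicate; Superdex-200-like SEC standards.
seed: 42
ptm:
  mod_type: phospho
  fdr_cutoff: 0.01
  isoform: 1N4R-P301S
  truth:
    202: 0.3
    231: 0.65
    262: 0.2
  samples: [week4, week6]
  draws_per_site: 200
  background_depth: 2
  decoy_fraction: 0.1
fret:
  gate_quantile: 0.995
  n_events: 20000
  replicates: 3
  control_condition: control
  conditions:
    control: 0.0
    week4: 0.05
    week6: 0.4
sec:
  monomer_mw_kda: 45.9
  sigma_log10: 0.02
render:
  color_zero: [0, 255, 255]
  color_one: [255, 0, 255]
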