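seed: 0
geometry:
  dv_height: 50.0
  ml_width: 20.0
  ap_length: 200.0
  canal_dv_frac: 0.3
  canal_ml_frac: 0.5
  somite_length: 25.0
  cell_diameter: 5.0
schedule:
  activation:
  - 24.0
  - 42.0
  consolidation:
  - 42.0
  - 66.0
  termination:
  - 66.0
  - 78.0
reporter:
  synthesis_rate: 10.0
  decay_rate: 0.028881132523331052
  maturation_lag: 0.0
  conversion_efficiency: 1.0
  detection_floor: 1.0
optics:
  voxel_size:
  - 1.0
  - 1.0
  - 1.0
  psf_sigma:
  - 1.0
  - 1.0
  - 1.0
  background_offset: 0.0
noise:
  photon_gain: 50.0
  read_noise_sigma: 2.0
  seed: 0
cohort:
  n_embryos: 8
  n_sections: 8
  cell_spacing_um: 2.5
  embryo_jitter_sigma: 0.03
  cell_noise_sigma: 0.1
timecourse_hours:
- 1.0
- 2.0
- 3.0
timecourse_markers:
- ptc2
- sox2
include_gli1_rescue: true
map_t0_grid: []
map_pathway: hh
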