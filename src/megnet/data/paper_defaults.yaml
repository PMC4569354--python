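# Full-scale defaults: every stage parameter at its study value.
# Scale the cohort and geometry down (see demo configs) for quick runs.
output_dir: megnet_run
seed: 0
geometry:
  head_radius: 0.09          # m, spherical conductor
  n_sensors: 275             # whole-head magnetometer helmet
  sensor_radius_factor: 1.2  # sensor shell at 1.2 x head radius
  grid_spacing: 0.01         # m, regular 3D source grid
simulation:
  n_patients: 13
  n_controls: 19
  n_epochs: 30               # randomly selected epochs per subject
  epoch_length_s: 10.0
  fs: 409.6                  # Hz, analysis sampling rate
  sensor_noise_sd: 5.0e-14   # T, white channel noise
  dipole_moment: 1.0e-8      # A·m
  planted_group_effect: 1.0  # 1.0 = exchangeable null cohort
  coupled_pairs: []
  active_nodes: []
preprocessing:
  bandpass_low: 0.5          # Hz, Butterworth band-pass
  bandpass_high: 70.0
  butter_order: 4
  marker_pad_s: 10.0         # s excised around each event marker
spectral:
  bands: [delta, theta, alpha, beta1, beta2, gamma]
  mode: center               # DPSS smoothing around the band centre
beamformer:
  lam: 0.05                  # 5% diagonal loading
graph:
  n_surrogates: 100
stats:
  node_t_threshold: 2.0
  node_alpha: 0.01
  nbs_t_threshold: 3.5
  nbs_alpha: 0.05
  power_t_threshold: 1.9
  power_alpha: 0.05
  n_permutations: 5000
  fdr_q: 0.05
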