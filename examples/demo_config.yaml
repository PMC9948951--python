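# Demo pipeline: 12 synthetic subjects, 8 gray-matter labels, 4 bundles.
# The sampling-cube edge is 7 voxels so the null's spatial unit is comparable
# to the desk-scale region sizes (the full-scale protocol uses 13 voxels).
design:
  on_seconds: 30
  off_seconds: 30
  n_blocks: 7
  n_dummy: 5
  tr: 3
simulate:
  grid_shape: [20, 20, 20]
  n_gm_labels: 8
  n_wm_bundles: 4
  n_subjects: 12
  amplitude_jitter: 0.2
  noise:
    sigma: 1.0
    ar1: 0.3
  tasks:
    sensory:
      responders:
        - {region: 1, shape: sustained, amplitude: 1.0}
        - {region: 2, shape: delayed, amplitude: 1.0}
        - {region: 3, shape: negative, amplitude: 1.0}
        - {region: bundle_00, shape: sustained, amplitude: 0.8}
bootstrap:
  n_boot: 500
  cube_edge: 7
  q_threshold: 0.01
seed: 11
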