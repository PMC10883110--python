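# Full analysis config. Either give `input_dir` (a directory of .tsv
# recordings with JSON sidecars, as written by `microdfc simulate`) or an
# inline `simulate` block.
simulate:
  duration: 300.0
  n_per_group: [16, 16]
  seed: 7
  coupling:
    - {state: 0, pair: [0, 1], group: MCS, strength: 0.8}
microstate_band: [2.0, 20.0]
preproc_band: [1.0, 40.0]
target_fs: 250.0
k_range: [4, 6]
window_s: 30.0
alpha: 0.01
n_tests: 496
mi:
  method: binned
  n_bins: 8
cv:
  outer_folds: 5
  inner_folds: 7
  unit: window
  classifier: {name: gbdt}
seed: 7
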