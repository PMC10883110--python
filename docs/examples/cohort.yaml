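# Synthetic cohort: 16 + 16 subjects, 5 minutes at 250 Hz, five microstates,
# two planted MCS-only couplings in state 0.
n_channels: 32
fs: 250.0
duration: 300.0
k_states: 5
n_per_group: [16, 16]
noise_sd: 1.0
seed: 7
coupling:
  - {state: 0, pair: [0, 1], group: MCS, strength: 0.8}
  - {state: 0, pair: [4, 9], group: MCS, strength: 0.8}
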