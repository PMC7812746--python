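# Demo pipeline config: surrogate recordings for five stimulus conditions,
# trial coherence between one channel per area, DoC tables for the four
# standard comparisons.  Run with:
#   cerecoh run --config examples/surrogate_demo.yaml --outdir scratch/demo
mode: surrogate
seed: 7
analysis:
  freqs: {lo: 2.0, hi: 100.0, n: 30}
  cycles: 7
  alpha: 0.05
  window_mode: full
surrogate:
  n_channels_per_area: 1
  sampling_rate: 500.0
  n_trials: 100
  trial_length: 2.5
  onset_offset: 0.5
  pair: [0, 1]
  conditions:
    baseline: {shared_fraction: 0.05, shared_band: [30, 50]}
    air_puff: {shared_fraction: 0.6, shared_band: [30, 50], evoked: true}
    air_puff_pc: {shared_fraction: 0.6, shared_band: [4, 8], evoked: true}
    air_puff_pc_delay: {shared_fraction: 0.5, shared_band: [30, 50], evoked: true}
    pc: {shared_fraction: 0.5, shared_band: [4, 8]}
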