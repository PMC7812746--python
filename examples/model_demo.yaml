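# Demo pipeline config: laminar network simulation under the four drive
# conditions, coherence between deep S1 and superficial M1 proxies, DoC
# per comparison.  Run with:
#   cerecoh run --config examples/model_demo.yaml --outdir scratch/model_demo
mode: model
seed: 1000
analysis:
  freqs: {lo: 2.0, hi: 100.0, n: 30}
  alpha: 0.05
  window_mode: full
model:
  n_trials: 100
  epoch: 2.0
  burn: 0.5
  decimate: 10
  tn_drive: 6.0
  pc_drive: 6.0
  pair: [[S1, inf], [M1, sup]]
comparisons:
  - [air_puff, baseline]
  - [pc, baseline]
  - [air_puff, air_puff_pc]
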