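# Demo run: two agents, two time points, noiseless phantoms.
# mpioquant run --config configs/demo.yaml --out runs/demo --seed 1
seed: 1
n_per_group: 3
groups:
  - [targeted, 1]
  - [targeted, 2]
  - [control, 1]
  - [control, 2]
ce_fraction_targeted:
  core: 0.10
  borderzone: 0.05
ce_fraction_control: {}
ce_amplitude: 0.3
noise_sigma: 10.0
fit_method: nlls
segmentation_method: threshold
k: 2.0
n_sd: 2.0
stats_model: welch
write_volumes: false
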