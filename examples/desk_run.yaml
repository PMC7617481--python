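# Desk-scale end-to-end run: corpus -> training -> physiology -> report.
seed: 1
outdir: run_output
corpus:
  n_clips: 400
  patch_size: 16
train:
  n_epochs: 8
  learning_rate: 3.0e-4
receptive_fields:
  n_noise_frames: 10000
perturbation:
  n_grid: [0, 30]
  n_repeats: 5
  classes: [co_tuned, orthogonal]
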