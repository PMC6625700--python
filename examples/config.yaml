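# Desk-scale phantom run: 40 scans, tiny-profile networks, 3 epochs.
phantom:
  n_scans: 40
  volume_shape: [64, 128, 128]
  spacing_mm: [1.25, 0.9, 0.9]
  nodules_per_scan: [2, 5]
  diameter_mm_range: [5.0, 30.0]
  fp_candidates_per_scan: 11
  spiculation: 0.6
  noise_sd: 20.0
  split: [0.7, 0.1, 0.2]
um:
  lambda: 1.0
profile: tiny
train:
  learning_rate: 0.05
  weight_decay: 0.0005
  epochs: 3
  batch_size: 8
  rt_relu_sigma: 0.05
seed: 1
out_dir: runs/demo
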