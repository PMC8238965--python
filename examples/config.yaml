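# Full example pipeline configuration.
#
# Modes: plain (network only) | wt (despeckle first) | crf (refine after)
#        | full (both). Paths are created under `workdir`; phantoms are
#        regenerated there unless `data_dir` points at an existing dataset.
mode: full
workdir: runs/example
seed: 1

phantom:
  height: 64
  width: 64
  n_layers: 5
  n_pockets: 2
  pocket_scale_range: [4, 10]
  pocket_intensity: 0.15
  speckle_looks: 4.0
  seed: 0

n_patients: 25
scans_per_patient: 8
split: [0.6, 0.2, 0.2]   # train / val / test fractions, patient level

denoise:
  alpha: 0.6745          # NT = median(|coeff|) / alpha (MAD convention)
  levels: 2
  family: haar
  band_policy: details   # details | low | all
  threshold_scope: per-image

net:
  n_stages: 2
  blocks_per_stage: 2
  base_channels: 16
  atrous_rates: [2, 4, 8]
  n_classes: 2
  input_size: [64, 64]

train:
  lr0: 0.007
  power: 0.9             # poly schedule exponent
  momentum: 0.9
  weight_decay: 5.0e-4
  epochs: 20
  batch_size: 8
  seed: 0
  class_weights: [1.0, 4.0]

crf:
  theta_alpha: 16.0      # spatial reach, px
  theta_beta: 8.0        # appearance tolerance, gray levels (0-255)
  kernel_weights: [3.0]
  n_iterations: 10
  inference_mode: auto   # dense | filtered | auto
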