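# Full six-variant ensemble configuration for `slseg run --config`.
# Omitted keys fall back to the library defaults (which are these values).
seed: 1
k: 5                      # cross-validation folds per variant
epochs: 8                 # training epochs per base learner
batch_size: 16
lr: 0.001
sl_epochs: 200            # Super Learner weight-fit epoch budget
threshold: 0.5            # probability threshold for the final mask
fractions: [0.80, 0.09, 0.11]   # train / tune / test
out_dir: scratch/slseg_run

phantom:                  # synthetic cohort (replace with your own exams)
  n_exams: 60
  shape: [8, 64, 64]
  seed: 0

variants:                 # the six base-learner variants
  - {method: zscore, bias_correct: false, unet: {levels: 3, root_features: 4}}
  - {method: zscore, bias_correct: true, unet: {levels: 3, root_features: 4}}
  - {method: minmax_volume, bias_correct: true, unet: {levels: 3, root_features: 4}}
  - {method: minmax_slice, bias_correct: true, unet: {levels: 3, root_features: 4}}
  - {method: nyul, bias_correct: true, unet: {levels: 3, root_features: 4}}
  - {method: zscore, bias_correct: true,
     unet: {levels: 3, root_features: 4, attention: true}}

augmentation:
  rotation_max_deg: 15.0
  scale_range: [0.9, 1.1]
  flip_h_prob: 0.5
  flip_v_prob: 0.5
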