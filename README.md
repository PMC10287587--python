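# slseg — Super Learner ensemble segmentation of lipomatous tumors in MRI

Lipomatous tumors (benign lipomas through liposarcomas) appear in
musculoskeletal MR images whose intensities mean different things on every
scanner: acquisition protocols differ between sites, coil inhomogeneity adds
a smooth multiplicative bias field, and no single intensity normalization
suits all exams. A segmentation network trained on one preprocessing
convention is therefore unstable across such heterogeneous data.

`slseg` implements a stacked-generalization ("Super Learner") answer to this
problem, aimed at researchers building robust segmentation pipelines for
multicenter MR data:

1. **Preprocessing variants.** N4-style bias-field correction combined with
   four normalizations — z-score, volume min–max, per-slice min–max, and
   Nyul histogram-landmark standardization — define six base-learner
   variants (five on a U-Net, one on an attention U-Net).
2. **Cross-validated base learners.** Each variant is trained slice-wise
   with a dice loss under K-fold cross-validation (K = 5), giving
   m = 6 × 5 = 30 base learners p_j.
3. **Super Learner.** On a held-out tuning split, the per-voxel probability
   maps are combined as p_SL,i = Σ_j w_j p_ji and the weights w are fit by
   minimizing the stacked cross-entropy

   Loss_SL(w) = − Σ_i [ y_i log Σ_j w_j p_ji + (1 − y_i) log(1 − Σ_j w_j p_ji) ]

   subject to the simplex constraints w_j ∈ [0, 1], Σ_j w_j = 1 (enforced by
   a softmax reparameterization). The final mask is p_SL thresholded at 0.5.
4. **Evaluation.** DSC, sensitivity, specificity, 95th-percentile Hausdorff
   distance (HD95, in mm, honoring anisotropic voxel spacing) and voxelwise
   ROC AUC, reported per exam and summarized per tumor location
   (DUL/DLL/PUL/PLL/T).

Because clinical cohorts of this kind are not shareable, the package ships a
seeded synthetic-phantom generator (`slseg.phantom`) that reproduces the
statistical structure the method targets — bias fields, site-dependent
intensity conventions, variable tumor size/contrast/position, noise — so the
entire pipeline is exercised end-to-end without any data download. The
neural-network layer (`slseg.nn`) is a compact CPU engine (im2col
convolutions, explicit backprop, Adam) sized so the desk-scale configuration
(3-level U-Net, root feature 4, 64×64 slices) trains in seconds.

## Worked example

`python examples/04_super_learner_weights.py` fits Super Learner weights for
four toy base learners (one nearly perfect, three noise) and prints:

```
fitted simplex weights:
  noise-a    0.0005
  good       0.9985
  noise-b    0.0005
  noise-c    0.0005
(sum = 1.000000, converged after 600 epochs)

per-voxel stacked cross-entropy (lower is better):
  optimized weights: 0.0520
  uniform weights:   0.5048
  noise-a alone:      1.0364
  good alone:      0.0513
  noise-b alone:      0.9789
  noise-c alone:      0.9635
```

The fit concentrates the weight on the informative learner and the optimized
combination attains essentially the best single-learner loss, an order of
magnitude below naive equal-weight averaging — the mechanism by which the
ensemble absorbs base-learner instability on heterogeneous data.

The other scripts in `examples/` walk through the remaining capabilities:
synthetic cohort generation, the preprocessing variants, training a base
learner, the metric suite, and the full pipeline
(`examples/06_full_pipeline.py`, a few minutes on one CPU).
`examples/pipeline.yaml` documents the configuration schema for the CLI:

```sh
slseg run --config examples/pipeline.yaml      # full 6-variant x 5-fold run
slseg phantom --out cohort/                    # write a NIfTI phantom cohort
slseg ingest --image t1.nii.gz --mask seg.nii.gz --out cache/
slseg split --cohort cache/ --fractions 0.80 0.09 0.11 --seed 1
```

## Layout

- `src/slseg/core.py` — domain types, NIfTI/DICOM/raw I/O, resampling, splits
- `src/slseg/preprocess.py` — bias correction and the four normalizations
- `src/slseg/phantom.py` — seeded synthetic multicenter cohort generator
- `src/slseg/nn/` — minimal CPU network engine (layers, U-Net, Adam)
- `src/slseg/models.py` — base learners: configs, dice loss, augmentation,
  training, cross-validation
- `src/slseg/ensemble.py` — the Super Learner (loss, weight fit, combination)
- `src/slseg/metrics.py` — DSC/sensitivity/specificity, HD95, ROC, summaries
- `src/slseg/workflow.py` — config-driven end-to-end orchestration
- `docs/methods.md` — model assumptions, parameter choices, limitations
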