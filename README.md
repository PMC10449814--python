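# savseg

Semantic segmentation of savanna tree species from very-high-resolution RGB
orthomosaics — as a fully testable, desk-scale pipeline.

Savanna woody vegetation is monitored over large areas with UAV imagery:
orthomosaics at ~1.2 cm ground sampling distance are delineated into a
dominant bare-ground/herb background plus many strongly imbalanced tree
species classes, and an encoder–decoder CNN assigns a species label to
every pixel.  This package implements that entire analysis chain for
ecologists and remote-sensing researchers who want to study, test, or
extend the method without field data:

- **Synthetic scenes** with the field data's statistical structure
  (imbalanced patchy classes, leaf-scale texture, seeded and reproducible),
  plus an appearance-drift perturbation emulating a seasonal re-survey.
- **Reference-data preparation**: non-overlapping square tiling,
  whole-scene train/validation/test splits (protecting evaluation from
  spatial autocorrelation), and label-consistent on-the-fly augmentation.
- **Class-imbalance-aware training**: per-class weights w_i = p_i^(−x),
  weighted categorical cross-entropy, Adam, early stopping on validation
  mIoU, and epoch selection on a LOESS-smoothed learning curve.  U-Net,
  FC-DenseNet and DeepLabv3+ are implemented at configurable scale on a
  numpy autodiff core — no GPU or deep-learning framework required.
- **Ensemble inference**: 16 prediction layers on tile grids offset by
  {0, 25, 50, 75}% of the tile size in each axis, combined by per-pixel
  majority vote.
- **Evaluation**: confusion matrix, per-class precision/recall/F1
  (F1 = 2PR/(P+R)), mean F1, overall accuracy, Cohen's κ, mIoU
  (mean over classes of |truth ∩ pred| / |truth ∪ pred|), paired t-tests
  across model configurations.
- **Landscape analysis**: per-class patch metrics (mean patch area, total
  class area, compactness 1 − a_patch/a_circle from the smallest
  circumscribing circle) and OLS regressions of class F1 on each metric.

See `docs/methods.md` for the model and all numerical conventions.

## Worked example

```python
from savseg.pipeline import desk_config, run_experiment, temporal_transfer_eval

config = desk_config("runs/demo", seed=1)      # 3-class scenes, small U-Net
results = run_experiment(config)
cell = results["cells"]["unet_t64"]
print(f"mean F1 {cell['mean_f1']:.3f}  OA {cell['overall_accuracy']:.3f}  "
      f"kappa {cell['kappa']:.3f}  mIoU {cell['miou']:.3f}")
for row in temporal_transfer_eval(results, [0.0, 0.5, 1.0]):
    print(f"drift {row['strength']:.1f}: mean F1 {row['mean_f1']:.3f}")
```

prints (a few minutes on one CPU):

```
mean F1 0.994  OA 0.995  kappa 0.991  mIoU 0.988
drift 0.0: mean F1 0.994
drift 0.5: mean F1 0.928
drift 1.0: mean F1 0.377
```

The model reads the held-out test scene almost perfectly (mean F1 0.99,
κ 0.99), and its accuracy collapses as the classes' appearance drifts away
from the training season — the same qualitative failure mode a CNN shows
when applied to imagery recorded months after its training data.

The numbered scripts under `analysis/` tell the same story step by step
(scene simulation and class shares, tiling and the block split, training
two architectures, per-class F1 and landscape regressions, the temporal
transfer ladder) and write their tables under `results/`.  A command-line
interface is also available (`savseg --help`: simulate, tile, run-all,
predict, evaluate, class-metrics, transfer-eval).

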