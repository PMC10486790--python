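# drfusion

Hybrid diabetic-retinopathy (DR) grading from color fundus photographs.

Diabetic retinopathy is graded clinically into five stages — normal, mild,
moderate and severe non-proliferative DR, and proliferative DR — by the
lesions visible on the retina: microaneurysms appear first, then hemorrhages
and exudates, and finally neovascularization. `drfusion` implements a
complete grading pipeline built on *fused* features: handcrafted color and
texture descriptors concatenated with deep-style embeddings, classified by
either a support-vector machine or a small feed-forward neural network.

## The pipeline

1. **Enhancement.** Gray-world color constancy, then the green channel *g*
   (strongest microvasculature contrast), then filter fusion

   `enhanced = mean_4x4(g) − ∇²g`

   i.e. a 4×4 box-filtered copy minus the 4-neighbor Laplacian, which
   denoises while sharpening vessel edges and dark lesions.
2. **Dataset design.** The normal class of the public grading corpora is
   subsampled to 10%; per class the data are split 64/16/20% into
   train/validation/test (round-half-up); the training partition is balanced
   by fixed per-class augmentation factors (normal ×3, mild ×3, moderate ×1,
   severe ×11, proliferative ×13 extra images per original) using small
   rotations, flips and shifts.
3. **Handcrafted features (232).** A 16-bin fuzzy color histogram (FCH) on
   the constancy-corrected RGB image, the 13 Haralick statistics of the
   gray-level co-occurrence matrix (GLCM), and a 203-bin uniform local
   binary pattern (LBP) histogram, the latter two on the enhanced image.
4. **Embeddings (4096 → ≤1024).** A seeded random convolution/pooling filter
   bank produces deterministic 4096-dim deep-style embeddings (a pretrained
   backbone can be slotted in behind the same contract); PCA reduces them to
   at most 1024 components.
5. **Classification.** Either *hybrid-SVM* (embedding → PCA → RBF SVM) or
   *fusion-FFNN* (PCA-reduced embedding ‖ 232 handcrafted → single hidden
   layer of 15 logistic units → softmax over the 5 grades).
6. **Evaluation.** 5×5 confusion matrix; one-vs-rest accuracy, precision,
   sensitivity, specificity (macro-averaged, in %), micro accuracy, and ROC
   AUC.

A seeded synthetic fundus generator (`drfusion.synthetic`) draws
stage-dependent lesions on a vessel-tree background so the whole pipeline is
testable without any external data.

## Worked example

```python
from drfusion import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1, n_per_class=50,
                                     model_path="fusion-ffnn"))
print(report)
```

prints (synthetic corpus, 50 images per class at 128×128, 10 test images
per class):

```
accuracy      84.80%  (micro 62.00%)
precision     72.11%
sensitivity   62.00%
specificity   90.50%
auc [roc]    92.65%
per-class accuracy (recall): normal=40.0%, mild=80.0%, moderate=30.0%, severe=90.0%, proliferative=70.0%
```

`accuracy` is the macro one-vs-rest accuracy over the five grades; `micro`
is plain fraction-correct. Adjacent grades differ only in lesion density, so
most residual confusion is between neighboring stages — exactly the hard
part of DR grading. Larger corpora (100+/class) raise both numbers.

The same run is available from the shell:

```bash
drfusion pipeline --model-path fusion-ffnn --n-per-class 50 --seed 1 --outdir runs/demo
```

which also writes the manifest, split/augmentation plans, confusion matrix,
metrics JSON and a provenance record (config hash + seed + versions) under
`runs/demo/`. Other subcommands (`synth`, `enhance`, `curate`, `split`,
`augment`, `evaluate`) expose the individual stages.

## Layout

| module | contents |
|---|---|
| `drfusion.preprocess` | color constancy, mean/Laplacian filters, `FundusEnhancer` |
| `drfusion.handcrafted` | FCH, GLCM/Haralick, LBP, `HandcraftedExtractor` |
| `drfusion.embeddings` | filter bank, pooling, PCA, `FilterBankEmbedder`, `PCAReducer` |
| `drfusion.datasetops` | curation, split plans, augmentation |
| `drfusion.models` | `HybridSVMClassifier`, `FusionFFNNClassifier`, feature fusion |
| `drfusion.evaluation` | confusion matrix, metric report |
| `drfusion.synthetic` | seeded synthetic fundus corpus generator |
| `drfusion.pipeline` / `drfusion.cli` | end-to-end orchestration and CLI |

See `docs/methods.md` for the scientific and numerical details.
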