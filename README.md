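# neurofuse

Multimodal classification of two-group neuroimaging cohorts from
resting-state fMRI and PET, with autoencoder-pretrained neural networks
and weight-based ROI interpretation.

## The problem

Chronic mild traumatic brain injury (mTBI) rarely shows on conventional
structural imaging, but it alters brain *function*: spontaneous activity,
local synchrony, network connectivity and glucose metabolism. This
package implements an individual-level classification analysis for such
cohorts:

1. **Voxelwise rs-fMRI metrics** per subject — fALFF (band-limited
   spectral amplitude fraction), ReHo (Kendall's W over the 26-voxel
   neighbourhood), degree centrality (DC, sum of Fisher-z weights over
   correlations r > 0.25), functional connectivity strength (FCS, mean
   Fisher-z over r > 0.2, normalised by mask size) and VMHC
   (interhemispheric mirror-voxel correlation) — plus **PET SUVR**
   (uptake normalised by a cerebellar reference region).
2. **ROI features**: each map averaged over the labels of an atlas
   (116-region AAL-style, or any integer-labelled NIfTI volume).
3. **Classification**: per modality, an autoencoder learns a latent
   representation of the min-max-scaled features; its encoder seeds an
   MLP (ReLU hidden layers 62/32/16, sigmoid output) trained with Adam at
   batch size 1 under patience-5 early stopping. A multimodal variant
   concatenates the frozen per-modality latents before a fresh MLP.
4. **Evaluation & interpretation**: stratified fivefold cross-validation
   (AUC, accuracy, sensitivity, specificity, precision, recall, F1), and
   ROI importance as the row-wise sum of absolute first-layer weights,
   aggregated across folds by top-10 selection frequency.

Since cohorts of this kind are typically private, a first-class
**synthetic cohort generator** produces BOLD-like 4D volumes, motion
traces and PET volumes for two groups, with effects of known Cohen's d
planted in known ROIs along metric-specific axes (band-limited amplitude,
local synchrony, hub connectivity, interhemispheric coupling, PET mean).
Every stage of the pipeline is tested end to end against that ground
truth. See `docs/methods.md` for the full model description.

## Worked example

Generate a synthetic cohort with a PET effect (d = 1.5) planted in five
of twenty ROIs, classify it with the PET single-modality model, and ask
which ROIs the network relied on:

```python
import neurofuse as nf

atlas = nf.generate_symmetric_atlas((16, 16, 12), n_rois=20, seed=5)
targets = nf.suggest_target_rois(atlas, 5, seed=5)
effect = nf.EffectSpec(target_rois=targets,
                       effect_axes=("pet_mean",), effect_size=1.5)
bundle = nf.generate_cohort(40, 40, effect=effect, seed=5)

result = nf.run_cohort_experiment(bundle, modalities=("suvr",),
                                  mode="single", cfg=nf.TrainConfig(seed=5))
print("planted ROIs:", sorted(targets))
print("top-10 by weight:", result.rankings["suvr"].final_rois)
for name, value in result.mean_scores().items():
    print(f"{name:12s} {100 * value:5.1f} %")
```

Output:

```
planted ROIs: [1, 10, 11, 14, 16]
top-10 by weight: [10, 16, 11, 14, 5, 20, 1, 3, 8, 15]
auc           96.9 %
accuracy      92.5 %
sensitivity   92.5 %
specificity   92.5 %
precision     93.1 %
recall        92.5 %
f1            92.5 %
```

All five planted ROIs appear in the final top-10, and the cross-validated
scores show the planted d = 1.5 effect is comfortably detectable at
40 + 40 subjects. With no planted effect the same pipeline yields AUC
near 50%, and fusing modalities with complementary effects beats either
single modality — both properties are asserted in the test suite.

A command-line interface mirrors the library:
`neurofuse simulate | prep | metrics | pet-suvr | roi-extract | folds |
train | evaluate | interpret | cohort-stats` (see `--help`).

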