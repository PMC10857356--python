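# crescentseg

One-click chronic subdural hematoma (CSDH) segmentation for head CT.

Chronic subdural hematoma — a liquefied blood collection between the dura
and the brain surface, crescent-shaped on axial CT and common in the
elderly — is managed largely on the basis of its volume. Measuring that
volume by hand means outlining the collection slice by slice, which takes
an expert the better part of an hour per study. `crescentseg` implements
the automated alternative as a library and CLI: a U-Net predicts a
per-pixel hematoma probability for every axial slice, the probability maps
are binarized at a threshold, and the mask yields the volume directly.

Two model variants are provided:

* **2D** — each 512x512 grayscale slice is segmented independently; at
  inference the slice and its left-right mirror are both predicted and the
  probability maps averaged (`(f(x) + mirror(f(mirror(x))))/2`);
* **2.5D** — the k ∈ {1, 3, 5} adjacent slices centred on the target are
  stacked as input channels, giving through-plane context without 3-D
  convolution.

Training uses soft Dice loss on the foreground softmax channel,

    L = 1 − (2 Σ p·t + s) / (Σ p + Σ t + s),

Adam (lr 1e-4, weight decay 1e-3), a per-epoch exponential lr schedule
(factor 0.96), 40 epochs, an 87.5% center crop and augmentation with
probability 0.4. Evaluation reports Dice `2|A∩B|/(|A|+|B|)` and Jaccard
`|A∩B|/|A∪B|` under covariate-stratified 10-fold cross-validation
(strata: embolization status x hematoma count), and mask volumetry in mL
with per-collection volumes from 26-connected components (bilateral
collections sum to the total).

Everything — network, backward passes, Adam — runs on numpy on one CPU and
is bit-deterministic per seed. Because clinical CT with CSDH annotations
is not redistributable, the package ships a synthetic phantom generator
(`crescentseg.phantom`): head-like volumes with an elliptical skull ring,
textured brain, and one or two analytically volumable crescent collections
flush against the inner skull, with ground-truth masks and covariates.
Every stage of the pipeline is trainable and testable on it end to end.

## Worked example

Train the 3-slice 2.5D variant on 14 synthetic series and segment 6
held-out ones (desk scale: 64x64, ~2 minutes on one CPU core):

```python
from crescentseg.evaluation import dice, hematoma_volume
from crescentseg.inference import binarize, predict_volume
from crescentseg.phantom import desk_spec, generate_cohort
from crescentseg.recipes import desk_model_config, desk_train_config
from crescentseg.unet_core import UNet, train
from crescentseg.volume_io import normalize_intensity

cohort = generate_cohort(20, None, base_spec=desk_spec(64, 16), seed=7)
train_set, held_out = cohort[:14], cohort[14:]

tcfg = desk_train_config(seed=3)
model = UNet(desk_model_config(k=3), seed=3)
model, history = train(model, train_set, tcfg)
print(f"train loss: {history[0]['train_loss']:.3f} -> {history[-1]['train_loss']:.3f}")

for s in held_out[:3]:
    vol = normalize_intensity(s.volume, *tcfg.window)
    prob = predict_volume(model, vol, k=3, use_tta=True, crop_fraction=tcfg.crop_fraction)
    mask = binarize(prob, 0.5)
    pred_ml, comps = hematoma_volume(mask)
    true_ml, _ = hematoma_volume(s.mask)
    print(f"{s.meta.series_id}: Dice {dice(mask, s.mask):.3f}, "
          f"predicted {pred_ml:.1f} mL ({len(comps)} component(s)), "
          f"reference {true_ml:.1f} mL")
```

Output:

```
train loss: 0.723 -> 0.183
s014: Dice 0.895, predicted 12.2 mL (2 component(s)), reference 10.3 mL
s015: Dice 0.893, predicted 16.8 mL (3 component(s)), reference 16.4 mL
s016: Dice 0.892, predicted 9.7 mL (1 component(s)), reference 7.9 mL
```

The Dice values say the predicted masks overlap the ground truth at ~0.9 —
good segmentation at this resolution — and the volumetry errors of 0.4–2 mL
are what that overlap implies for the clinical quantity of interest. Small
spurious extra components (s014, s015) are isolated false-positive voxel
clusters; no post-processing is applied by design.

The same workflow from the shell:

```bash
crescentseg simulate --out cohort/ --n-series 53 --seed 0      # synthetic dataset
crescentseg train    --input cohort/ --out model.npz --k 3
crescentseg predict  --model model.npz --input cohort/s000_ct.nii.gz \
                     --out mask.nii.gz --threshold 0.5
crescentseg crossval --input cohort/ --out report.csv          # 10-fold CV sweep
crescentseg evaluate --pred mask.nii.gz --truth cohort/s000_mask.nii.gz
```

All commands accept `--config <yaml>` overriding the shipped defaults (the
published hyperparameters) and write a JSON manifest recording config and
seed next to their outputs; identical invocations produce identical files.

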