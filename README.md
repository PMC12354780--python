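# uigo — two-stage liver-tumor segmentation and classification

`uigo` implements a desk-scale, fully testable version of a two-stage liver
tumor analysis pipeline for 2-D CT-like slices:

1. **Segmentation** — an inception-augmented U-Net: parallel 1×1/3×3/5×5
   encoder branches with residual aggregation, levelled 1×1 bottlenecks,
   a symmetric decoder fed by skip connections plus "historic stamp"
   projections of the cached encoder features, and a 1×1 sigmoid head.
   Training minimizes the tri-composite loss

   L = 0.27·FL + 0.69·DL + 0.04·HD

   where FL is focal loss −α_t(1−p_t)^γ log p_t, DL is soft Dice loss
   1 − 2|A∩B|/(|A|+|B|), and HD is a differentiable Hausdorff surrogate built
   from distance transforms (the exact symmetric Hausdorff
   H(A,B) = max(h(A,B), h(B,A)), h(A,B) = max_{a∈A} min_{b∈B} ‖a−b‖, is used
   for evaluation). Tversky and focal-Tversky variants (α = 0.7, β = 0.3,
   γ = 0.75) are included for ablation.

2. **Classification** — connected components of the predicted masks yield a
   16-feature radiomic-style row (geometry, intensity statistics, co-occurrence
   texture); a Gravitational Optimization (GO) wrapper search selects the
   feature subset and a LightGBM booster (learning rate 0.05, max depth 6,
   40 leaves) classifies each slice as tumor-bearing or not.

GO is a population metaheuristic in which candidate solutions attract each
other with forces proportional to fitness-derived masses under a decaying
gravitational constant G(t) = g₀·e^(−βt/T); a continuous variant tunes
hyperparameters and a binary variant (tanh transfer) searches feature subsets.

Everything runs on synthetic **phantoms**: elliptical "liver" slices
containing 0–3 irregular higher-intensity "tumor" blobs under Gaussian noise,
generated deterministically with paired label maps {0 = background, 1 = liver,
2 = tumor}. No external data or GPU is needed; the network trains through a
small numpy reverse-mode autodiff engine included in the package.

## Worked example

```python
from pathlib import Path
from uigo import prep
from uigo.phantom_forge import PhantomSpec, forge_dataset, load_manifest
from uigo.pipeline import PrepSettings, TrainConfig, build_arrays, train_segmenter
from uigo.uigo_net import NetConfig

root = Path("runs/demo")
forge_dataset(PhantomSpec(seed=1), 200, root)              # 200 phantom slices
manifest = prep.assign_splits(load_manifest(root), seed=1)  # 140/40/20 split
images, masks, ids, splits = build_arrays(root, manifest, PrepSettings())
net, history = train_segmenter(
    images, masks, splits,
    NetConfig(input_size=64, levels=2, base_filters=8, dropout=0.1, seed=1),
    TrainConfig(batch_size=8, epochs=12, early_stop_patience=6, seed=1))
print(history[["epoch", "train_total", "val_dice"]].tail(3).to_string(index=False))
print("best validation Dice:", history["best_val_dice"].iloc[-1])
```

prints (about two minutes on one CPU core):

```
 epoch  train_total  val_dice
     9     0.427685  0.963831
    10     0.396283  0.972136
    11     0.363588  0.978645
best validation Dice: 0.9786449535759288
```

i.e. the small network reaches a validation Dice of ≈ 0.98 against the
phantom ground truth — `val_dice` is the mean thresholded-overlap score over
the 40 validation slices, and `train_total` is the tri-composite loss.

The same flow is available from the shell:

```bash
uigo run --config configs/desk.yaml     # forge → train → features → GO → classify
uigo describe --config configs/desk.yaml
```

`configs/desk.yaml` is the CPU-friendly profile (64×64 slices, 2 levels);
`configs/paper.yaml` mirrors the full-scale settings (512×512, 4 levels,
batch 32, GO 25×100) and assumes long training.

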