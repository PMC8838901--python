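# s3cgan — stain style transfer for histological image patches

Digitized histology varies in color from lab to lab and scanner to
scanner (stain batches, section thickness, optics). These shifts hurt
automated analysis trained on one appearance. `s3cgan` learns a mapping
between two stain appearances from **unpaired** patch collections and
applies it while preserving tissue structure.

The model is a cycle-consistent adversarial translator with a color
consultant:

* **U-Net generators** `G_A2B`, `G_B2A` (skip connections at every
  level, tanh output) for pixel-level structural fidelity;
* **Markovian (patch) critics** `D_A`, `D_B` producing an N×N map of
  local Wasserstein scores, trained with a gradient penalty
  (`E[D(fake)] − E[D(real)] + 10·E[(‖∇ D(x̂)‖₂ − 1)²]`);
* a **specialized color classifier** `C_color` — a small binary network
  pretrained to tell the two stain appearances apart, then frozen. Its
  cross-entropy on generated patches joins the generator objective

  `L_obj = L_adv + α·L_cyc + β·L_color`,  α = 10, β = 1,

  supplying trustworthy color feedback during the earliest, least
  stable phase of adversarial training.

A synthetic two-style fixture generator (elliptical nuclei over stromal
texture, Beer–Lambert stain rendering) makes the whole pipeline
exercisable — including paired ground truth and binary density labels —
without any slide data.

## Worked example

```python
import numpy as np
from s3cgan import make_fixture_set, TrainingConfig, TrainingState
from s3cgan.training import pretrain_color_classifier, train
from s3cgan.evaluation import transfer_batch, compute_ssim, compute_psnr
from s3cgan.image_data import patches_to_batch, batch_to_patches

fx = make_fixture_set(n_per_domain=200, size=64, seed=7, n_paired=20)
cfg = TrainingConfig.desk_scale(seed=7)

clf, acc = pretrain_color_classifier(fx["pre_a"], fx["pre_b"], cfg)
print("clf acc", acc)                       # clf acc 1.0

state = TrainingState(cfg, clf)
src = patches_to_batch([p.patch_a for p in fx["paired_test"]])
p0 = clf.predict_proba(transfer_batch(state.g_a2b, src))[:, 1].mean()
state = train(fx["ds_a"], fx["ds_b"], cfg, c_color=clf, state=state)

out = transfer_batch(state.g_a2b, src)
p1 = clf.predict_proba(out)[:, 1].mean()
print(f"target prob {p0:.3f} -> {p1:.3f}")  # target prob 0.266 -> 1.000

tr = batch_to_patches(np.clip(out, -1, 1))
gt = [p.patch_b for p in fx["paired_test"]]
ssim_t = np.mean([compute_ssim(t, g) for t, g in zip(tr, gt)])
ssim_s = np.mean([compute_ssim(p.patch_a, g)
                  for p, g in zip(fx["paired_test"], gt)])
print(f"ssim transferred {ssim_t:.3f} vs source {ssim_s:.3f}")
# ssim transferred 0.714 vs source 0.687
```

Reading the numbers: after 600 generator steps the frozen color
classifier assigns the transferred patches probability ≈ 1.0 of being
target-style (up from 0.27 at initialization), and the transfers are
*structurally* closer to the ground-truth target rendering of the same
tissue than the untouched sources are (SSIM 0.714 > 0.687). The same
trained model lifts a target-style density classifier from AUC 0.83 on
raw source patches to 0.98 on their transfers — the downstream payoff
stain normalization exists for.

## Command line

```
s3cgan make-fixtures --n 200 --size 64 --seed 0 --out data/
s3cgan pretrain-classifier --data data/ --seed 0 --out clf.npz
s3cgan train --data data/ --config cfg.yaml --seed 0 --out run/
s3cgan transfer --model run/checkpoint.npz --in data/A/test --out out/
s3cgan evaluate --pairs manifest.csv
s3cgan describe
```

`cfg.yaml` mirrors `TrainingConfig` (step counts, α/β weights, network
widths, snapshot cadence). Datasets follow the layout
`root/{A,B}/{pretrain,train,test}/*.png`.

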