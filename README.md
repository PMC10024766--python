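# litesal

Lightweight salient-object detection for real-time bone localization in
livestock X-ray images.

Boning robots need to find the bone inside a pork-leg radiograph before
they can plan a cutting path, and they need to do it on industrial
controllers without a GPU. `litesal` implements a compact (2.1 M
parameter) saliency network for this task: a five-stage encoder whose
stages end in a **multiscale attention module** (three dilated-conv scale
branches gated by channel/spatial attention and a cross-branch softmax), a
decoder built from **full-scale skip connections** (each stage fuses
quarter-width, resized features from multiple encoder and decoder scales
plus a pyramid-pooled global feature), and a small **residual refinement
module** that cleans up region interiors and boundaries:

```
M_refine = sigmoid( logit(M_coarse) + RFM(M_coarse) )
```

The package also provides the standard saliency metrics — MAE, the
threshold-swept F-measure `F = (1+β²)PR / (β²P + R)` (β² = 0.3) and the
weighted Fωβ protocol — a seeded CPU training loop (Adam 3e-4, cosine
annealing, paired flips), a synthetic generator for blob scenes and
X-ray-style bone images, and a thin CLI. Everything runs on plain
numpy/scipy: the network's autodiff core is part of the package
(`litesal.nn`), so there is no deep-learning-framework dependency.

See `docs/methods.md` for the model and protocol details and
`examples/` for narrative walk-throughs.

## Worked example

Generate 16 synthetic X-ray scenes, overfit the detector, and score it
(abridged from `examples/03_train_and_evaluate.py`; a few minutes on one
CPU core):

```python
import numpy as np
from litesal import (ModelConfig, SaliencyNet, SynthConfig, TrainConfig,
                     gen_pairs, count_parameters)
from litesal.train import train_loop

pairs = gen_pairs(SynthConfig(n_images=16, seed=7))      # bone tubes, contrast 0.15
images = np.stack([p.image.transpose(2, 0, 1) for p in pairs])
masks  = np.stack([p.mask.astype(np.float32) for p in pairs])

model = SaliencyNet(ModelConfig(seed=0))
print(count_parameters(model))                            # 2.1  (millions)

cfg = TrainConfig(epochs=50, batch_size=4, seed=0)
_, log = train_loop(model, images, masks, cfg, max_steps=200, target_mae=0.05)
print(log.epochs[-1])
```

Output from this exact run:

```
2.1
{'epoch': 12, 'lr': 0.0002594..., 'mean_loss': 0.0602..., 'train_mae': 0.0480...}
```

2.1 is the trainable-parameter count in millions — the budget that makes
the model deployable on weak hardware. The final line shows the network
memorizing the 16 scenes: training MAE (mean absolute error against the
exact bone masks) falls below 0.05 within 52 optimizer steps, confirming
the architecture has the capacity to represent thin, low-contrast bone
tubes.

The command-line interface chains the same pieces:

```bash
litesal synth --mode xray --n 16 --seed 7 --out data/
litesal train --data data/ --out run/ --epochs 50 --seed 0
litesal predict --ckpt run/checkpoint.npz --in data/images --out preds/
litesal eval --pred preds/ --gt data/masks --out report.json
```

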