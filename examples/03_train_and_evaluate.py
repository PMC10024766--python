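"""Overfit the detector on a handful of synthetic scenes, then score it.

Trains the default network on 16 generated X-ray scenes (Adam 3e-4,
cosine annealing, paired flips) for up to 200 optimizer steps, prints the
loss/MAE trajectory, and evaluates the final model with the saliency
metrics (max-F, weighted-F, MAE).  Takes a few minutes on one CPU core.
"""

import numpy as np

from litesal import (
    ModelConfig, SaliencyNet, SynthConfig, TrainConfig,
    gen_pairs, max_f_measure, weighted_fbeta, mae, nn,
)
from litesal.nn import Tensor
from litesal.train import train_loop

pairs = gen_pairs(SynthConfig(n_images=16, seed=7))
images = np.stack([p.image.transpose(2, 0, 1) for p in pairs])
masks = np.stack([p.mask.astype(np.float32) for p in pairs])

model = SaliencyNet(ModelConfig(seed=0))
cfg = TrainConfig(epochs=50, batch_size=4, seed=0)
_, log = train_loop(model, images, masks, cfg, max_steps=200, target_mae=0.05)
for row in log.epochs:
    print(f"epoch {row['epoch']:2d}  lr {row['lr']:.2e}  "
          f"loss {row['mean_loss']:.4f}  train MAE {row['train_mae']:.4f}")

model.eval()
scores = []
with nn.no_grad():
    for i in range(4):
        _, refined = model(Tensor(images[i][None]))
        p = refined.data[0, 0].astype(np.float64)
        scores.append((max_f_measure(p, masks[i].astype(int)),
                       weighted_fbeta(p, masks[i].astype(int)),
                       mae(p, masks[i].astype(int))))
print("\nper-image (maxF, weighted-F, MAE) on the first 4 training scenes:")
for s in scores:
    print(f"  {s[0]:.3f}  {s[1]:.3f}  {s[2]:.4f}")
# Training MAE dropping under 0.05 means the network can represent and
# memorize the bone shapes; high F values on training scenes confirm the
# saliency maps align with the exact bone-tube ground truth.
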