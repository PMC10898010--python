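"""Train a small dilated multi-scale attention U-Net on synthetic pests.

Trains at desk scale (32x32 inputs, narrow widths) for a few hundred
Adam steps and reports the compound IoU+BCE loss trend plus training-set
ACC (= TP/(TP+FN)) and IoU (= TP/(TP+FP+FN)).  Takes a couple of
minutes on one CPU core.
"""

import numpy as np

from pestseg import (
    InceptionConfig,
    ModelConfig,
    SynthConfig,
    TrainConfig,
    evaluate,
    load_samples,
    train,
)

images, masks = load_samples(SynthConfig(n_images=10, size=(32, 32), seed=3))
model_cfg = ModelConfig(
    variant="dmsaunet", depth=2, base_channels=4, input_size=(32, 32, 3),
    attention_reduction=4, inception=InceptionConfig(bottleneck_channels=4),
)
train_cfg = TrainConfig(iterations=300, batch_size=8, eval_every=100, seed=3)

model, history = train(model_cfg, train_cfg, images, masks)
print(f"model: {model_cfg.variant}, {model.count_parameters()} trainable parameters")
print(f"loss: {history.step_loss[0]:.3f} (start) -> {np.median(history.step_loss[-30:]):.3f} (median, last 30 steps)")
rep = evaluate(model, images, masks)
print(f"training-set ACC = {rep['acc']:.3f}, IoU = {rep['iou']:.3f}")
print("(ACC is the recall-form TP/(TP+FN); IoU is the Jaccard index over pixels)")
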