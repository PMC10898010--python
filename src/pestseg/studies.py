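"""Canonical desk-scale studies: overfit convergence and variant ablation.

Full-scale training of this architecture (128 x 128 inputs, base width
64, thousands of iterations on thousands of images) is a GPU-scale
undertaking.  These two studies are the package's CPU-scale reference
protocols — fixed problem sizes chosen once so that each runs in minutes
on one core while still exercising the full pipeline end to end:

* the **overfit study** trains the full dilated multi-scale attention
  variant on a small synthetic set until it reproduces its own training
  masks (a capacity/convergence check: training IoU should exceed 0.9
  and the loss curve should fall);
* the **ablation study** cross-validates the plain U-Net against the
  full variant on shared folds across several seeds (a direction check:
  the multi-scale attention variant should not lose to the baseline).

Both are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import InceptionConfig
from .model import ModelConfig
from .synthetic import SynthConfig
from .training import TrainConfig, evaluate, run_ablation, train

__all__ = ["OverfitResult", "AblationResult", "overfit_study", "ablation_study"]

# problem sizes of the desk-scale protocols (fixed; see docs/methods.md)
OVERFIT_N_IMAGES = 12
OVERFIT_SIZE = (64, 64)
OVERFIT_MODEL = dict(variant="dmsaunet", depth=3, base_channels=8)
OVERFIT_TRAIN = dict(iterations=450, batch_size=6, eval_every=50)

ABLATION_N_IMAGES = 30
ABLATION_SIZE = (32, 32)
ABLATION_MODEL = dict(depth=2, base_channels=4, attention_reduction=4)
ABLATION_BOTTLENECK = 4
ABLATION_TRAIN = dict(iterations=850, batch_size=4, eval_every=200)
ABLATION_FOLDS = 5


@dataclass
class OverfitResult:
    train_iou: float
    train_acc: float
    loss_median_first: float  # median mini-batch loss, first 10% of steps
    loss_median_last: float  # median mini-batch loss, last 10% of steps
    n_images: int
    iterations: int


@dataclass
class AblationResult:
    mean_iou: dict[str, float]  # variant -> mean over seeds of CV-mean IoU
    mean_acc: dict[str, float]
    per_seed_iou: dict[str, list[float]]
    n_images: int
    seeds: tuple[int, ...]


def overfit_study(seed: int = 7) -> OverfitResult:
    """Train the full variant to convergence on a small synthetic set.

    Returns training-set metrics and the loss-trend summary (median
    mini-batch loss over the first versus last tenth of the steps).
    """
    from .synthetic import load_samples

    synth = SynthConfig(n_images=OVERFIT_N_IMAGES, size=OVERFIT_SIZE, seed=seed)
    images, masks = load_samples(synth)
    mcfg = ModelConfig(input_size=OVERFIT_SIZE + (3,), **OVERFIT_MODEL)
    tcfg = TrainConfig(seed=seed, **OVERFIT_TRAIN)
    model, history = train(mcfg, tcfg, images, masks)
    rep = evaluate(model, images, masks)
    tenth = max(1, len(history.step_loss) // 10)
    return OverfitResult(
        train_iou=rep["iou"],
        train_acc=rep["acc"],
        loss_median_first=float(np.median(history.step_loss[:tenth])),
        loss_median_last=float(np.median(history.step_loss[-tenth:])),
        n_images=OVERFIT_N_IMAGES,
        iterations=tcfg.iterations,
    )


def ablation_study(
    seeds: tuple[int, ...] = (0, 1, 2),
    variants: tuple[str, ...] = ("unet", "dmsaunet"),
    data_seed: int = 11,
) -> AblationResult:
    """Cross-validated variant comparison on shared folds, repeated per seed.

    The narrow desk-scale widths keep the branch bottlenecks at a fixed
    4 channels so the multi-scale block is not starved at base width 4.
    """
    from .synthetic import load_samples

    synth = SynthConfig(n_images=ABLATION_N_IMAGES, size=ABLATION_SIZE, seed=data_seed)
    images, masks = load_samples(synth)
    mcfg = ModelConfig(
        input_size=ABLATION_SIZE + (3,),
        inception=InceptionConfig(bottleneck_channels=ABLATION_BOTTLENECK),
        **ABLATION_MODEL,
    )
    per_iou: dict[str, list[float]] = {v: [] for v in variants}
    per_acc: dict[str, list[float]] = {v: [] for v in variants}
    for seed in seeds:
        tcfg = TrainConfig(seed=seed, **ABLATION_TRAIN)
        table = run_ablation(list(variants), mcfg, tcfg, images, masks, k=ABLATION_FOLDS)
        for _, row in table.iterrows():
            per_iou[row["variant"]].append(float(row["mean_iou"]))
            per_acc[row["variant"]].append(float(row["mean_acc"]))
    return AblationResult(
        mean_iou={v: float(np.mean(per_iou[v])) for v in variants},
        mean_acc={v: float(np.mean(per_acc[v])) for v in variants},
        per_seed_iou=per_iou,
        n_images=ABLATION_N_IMAGES,
        seeds=tuple(seeds),
    )
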