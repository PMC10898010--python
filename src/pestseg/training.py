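"""Seeded training loop, k-fold cross-validation, and the ablation driver.

Training follows the protocol this model family is evaluated under:
Adam (stochastic gradient descent with adaptive moment estimation) at a
constant learning rate, a fixed iteration budget (iterations are
optimizer steps, not epochs), mini-batches of 32, and 5-fold
cross-validation over mutually exclusive near-equal splits.  Everything
is a pure function of (configs, data, seed): weight init, batch
sampling and fold assignment all derive from explicit generators, so a
repeated run reproduces every reported number bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._tensor import Tensor
from .model import Model, ModelConfig, VARIANTS, build_model
from .objective import (
    ConfusionCounts,
    accuracy,
    boundary_weight_map,
    confusion_from_masks,
    iou,
    total_loss,
    weighted_bce_loss,
)

__all__ = [
    "TrainConfig",
    "History",
    "EvalReport",
    "kfold_split",
    "train",
    "evaluate",
    "run_cv",
    "run_ablation",
    "Adam",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer hyperparameters and training protocol.

    Defaults follow the standard recipe for this task: Adam with
    learning rate 1e-3, decay factors (0.9, 0.999), batch size 32, 3000
    iterations.  ``loss_mode`` selects the compound IoU+BCE objective
    (``"eq_sum"``) or plain cross-entropy (``"bce"``); ``weight_mode``
    selects uniform or boundary-emphasis pixel weights.
    """

    iterations: int = 3000
    batch_size: int = 32
    learning_rate: float = 1e-3
    grad_decay: float = 0.9
    sq_grad_decay: float = 0.999
    optimizer: str = "adam"
    loss_mode: str = "eq_sum"  # "eq_sum" (IoU + BCE) | "bce"
    weight_mode: str = "uniform"  # "uniform" | "boundary"
    boundary_lambda: float = 5.0
    augment: bool = False  # random flips / 90-degree rotations per batch
    seed: int = 0
    eval_every: int = 100

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        for name in ("grad_decay", "sq_grad_decay"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss_mode not in ("eq_sum", "bce"):
            raise ValueError(f"loss_mode must be 'eq_sum' or 'bce', got {self.loss_mode!r}")
        if self.weight_mode not in ("uniform", "boundary"):
            raise ValueError(f"weight_mode must be 'uniform' or 'boundary', got {self.weight_mode!r}")
        if self.eval_every < 1:
            raise ValueError("eval_every must be >= 1")


@dataclass
class History:
    """Loss/metric snapshots over training; iterations strictly increasing.

    ``step_loss`` additionally traces the mini-batch loss of every single
    optimizer step (``step_loss[i]`` is the loss *before* update ``i+1``),
    for loss-versus-iteration curves and convergence analysis.
    """

    iterations: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    step_loss: list[float] = field(default_factory=list)

    def append(self, it: int, loss: float, acc: float | None, jac: float | None):
        if self.iterations and it <= self.iterations[-1]:
            raise ValueError("history iterations must be strictly increasing")
        self.iterations.append(int(it))
        self.train_loss.append(float(loss))
        self.val_acc.append(float("nan") if acc is None else float(acc))
        self.val_iou.append(float("nan") if jac is None else float(jac))


@dataclass
class EvalReport:
    """Per-fold and mean metrics for one model variant."""

    variant: str
    fold_acc: list[float]
    fold_iou: list[float]

    @property
    def mean_acc(self) -> float:
        return float(np.mean(self.fold_acc))

    @property
    def mean_iou(self) -> float:
        return float(np.mean(self.fold_iou))


# ---------------------------------------------------------------------------
# cross-validation splits
# ---------------------------------------------------------------------------

def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Random partition of ``range(n)`` into k disjoint near-equal folds.

    A seeded uniform permutation is chunked so fold sizes differ by at
    most one; the folds cover every index exactly once.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive moment estimation on a dict of parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float, beta1: float, beta2: float,
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def _augment_batch(images: np.ndarray, masks: np.ndarray, rng: np.random.Generator):
    """Random horizontal/vertical flips and square 90-degree rotations."""
    images = images.copy()
    masks = masks.copy()
    square = images.shape[1] == images.shape[2]
    for i in range(images.shape[0]):
        if rng.random() < 0.5:
            images[i] = images[i, :, ::-1]
            masks[i] = masks[i, :, ::-1]
        if rng.random() < 0.5:
            images[i] = images[i, ::-1]
            masks[i] = masks[i, ::-1]
        if square:
            k = int(rng.integers(0, 4))
            images[i] = np.rot90(images[i], k)
            masks[i] = np.rot90(masks[i], k)
    return images, masks


def _batch_loss(model: Model, images: np.ndarray, masks: np.ndarray,
                cfg: TrainConfig):
    pred = model.forward(Tensor(images))
    target = Tensor(masks[..., None].astype(np.float64))
    if cfg.weight_mode == "boundary":
        w = np.stack([boundary_weight_map(m, cfg.boundary_lambda) for m in masks])
        weights = Tensor(w[..., None])
    else:
        weights = None
    if cfg.loss_mode == "bce":
        return weighted_bce_loss(pred, target, weights)
    return total_loss(pred, target, weights)


def train(
    model_config: ModelConfig,
    train_config: TrainConfig,
    images: np.ndarray,
    masks: np.ndarray,
    val_images: np.ndarray | None = None,
    val_masks: np.ndarray | None = None,
    model: Model | None = None,
) -> tuple[Model, History]:
    """Train a model on (images, masks); returns the model and its History.

    Batches are drawn with replacement when the dataset is smaller than
    the batch size, otherwise by cycling a seeded shuffle.  A loss
    snapshot is recorded at iteration 0 and every ``eval_every`` steps
    (with validation metrics when a validation set is given).  A
    non-finite loss aborts with a diagnostic.
    """
    images = np.asarray(images, dtype=np.float64)
    masks = np.asarray(masks)
    n = images.shape[0]
    if n == 0:
        raise ValueError("training data is empty")
    if model is None:
        model = build_model(model_config, seed=train_config.seed)
    rng = np.random.default_rng(np.random.SeedSequence(train_config.seed, spawn_key=(1,)))
    opt = Adam(
        model.params,
        lr=train_config.learning_rate,
        beta1=train_config.grad_decay,
        beta2=train_config.sq_grad_decay,
    )
    history = History()
    bs = train_config.batch_size
    order = rng.permutation(n)
    cursor = 0

    def next_batch() -> np.ndarray:
        nonlocal order, cursor
        if n < bs:
            return rng.integers(0, n, size=bs)
        if cursor + bs > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + bs]
        cursor += bs
        return idx

    def snapshot(it: int, loss_val: float) -> None:
        acc = jac = None
        if val_images is not None and val_masks is not None:
            rep = evaluate(model, val_images, val_masks)
            acc, jac = rep["acc"], rep["iou"]
        history.append(it, loss_val, acc, jac)

    idx0 = next_batch() if train_config.iterations > 0 else np.arange(min(n, bs))
    loss0 = _batch_loss(model, images[idx0], masks[idx0], train_config)
    snapshot(0, loss0.item())
    if train_config.iterations == 0:
        return model, history

    for it in range(1, train_config.iterations + 1):
        if it == 1 and not train_config.augment:
            loss = loss0  # reuse the graph already built for the snapshot
        else:
            idx = next_batch()
            bi, bm = images[idx], masks[idx]
            if train_config.augment:
                bi, bm = _augment_batch(bi, bm, rng)
            loss = _batch_loss(model, bi, bm, train_config)
        lv = loss.item()
        if not np.isfinite(lv):
            raise RuntimeError(
                f"non-finite loss {lv} at iteration {it}; "
                f"last snapshot: {history.train_loss[-1] if history.train_loss else None}"
            )
        history.step_loss.append(lv)
        loss.backward()
        opt.step()
        if it % train_config.eval_every == 0 or it == train_config.iterations:
            if history.iterations[-1] != it:
                idx = next_batch()
                cur = _batch_loss(model, images[idx], masks[idx], train_config)
                snapshot(it, cur.item())
    return model, history


def evaluate(
    model: Model,
    images: np.ndarray,
    masks: np.ndarray,
    threshold: float = 0.5,
    batch: int = 8,
) -> dict:
    """Pixel-pooled (micro) metrics of a model on a labelled set.

    Returns ``acc``/``iou`` micro-averaged over all pixels plus
    ``mean_acc``/``mean_iou`` averaged per image (images whose metric is
    undefined — no foreground anywhere — are skipped in the per-image
    means).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    images = np.asarray(images, dtype=np.float64)
    masks = np.asarray(masks)
    if images.shape[0] == 0:
        raise ValueError("evaluation set is empty")
    totals = ConfusionCounts(0, 0, 0, 0)
    per_acc: list[float] = []
    per_iou: list[float] = []
    for start in range(0, images.shape[0], batch):
        probs = model.predict(images[start : start + batch])
        preds = (probs >= threshold).astype(np.uint8)
        for p, t in zip(preds, masks[start : start + batch]):
            c = confusion_from_masks(p, t)
            totals = totals + c
            if c.tp + c.fn > 0:
                per_acc.append(accuracy(c))
            if c.tp + c.fp + c.fn > 0:
                per_iou.append(iou(c))
    return {
        "acc": accuracy(totals),
        "iou": iou(totals),
        "mean_acc": float(np.mean(per_acc)) if per_acc else float("nan"),
        "mean_iou": float(np.mean(per_iou)) if per_iou else float("nan"),
        "confusion": totals,
    }


def run_cv(
    model_config: ModelConfig,
    train_config: TrainConfig,
    images: np.ndarray,
    masks: np.ndarray,
    k: int = 5,
    folds: list[np.ndarray] | None = None,
) -> tuple[EvalReport, list[History]]:
    """k-fold cross-validation: train k models, score each held-out fold."""
    n = np.asarray(images).shape[0]
    if folds is None:
        folds = kfold_split(n, k, train_config.seed)
    fold_acc: list[float] = []
    fold_iou: list[float] = []
    histories: list[History] = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        fold_cfg = replace(train_config, seed=train_config.seed + 1000 * i)
        m, h = train(model_config, fold_cfg, images[train_idx], masks[train_idx])
        rep = evaluate(m, images[test_idx], masks[test_idx], threshold=model_config.threshold)
        fold_acc.append(rep["acc"])
        fold_iou.append(rep["iou"])
        histories.append(h)
    return EvalReport(model_config.variant, fold_acc, fold_iou), histories


def run_ablation(
    variants: list[str],
    model_config: ModelConfig,
    train_config: TrainConfig,
    images: np.ndarray,
    masks: np.ndarray,
    k: int = 5,
):
    """Run the same CV protocol for several variants on shared fold splits.

    Returns a pandas DataFrame with one row per requested variant, in
    request order, reporting per-fold and mean ACC / IoU.
    """
    import pandas as pd

    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}; choose from {sorted(VARIANTS)}")
    n = np.asarray(images).shape[0]
    folds = kfold_split(n, k, train_config.seed)
    rows = []
    for v in variants:
        cfg = replace(model_config, variant=v)
        report, _ = run_cv(cfg, train_config, images, masks, k=k, folds=folds)
        rows.append(
            {
                "variant": v,
                "mean_acc": report.mean_acc,
                "mean_iou": report.mean_iou,
                "fold_acc": report.fold_acc,
                "fold_iou": report.fold_iou,
            }
        )
    return pd.DataFrame(rows, columns=["variant", "mean_acc", "mean_iou", "fold_acc", "fold_iou"])
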