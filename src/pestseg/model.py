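"""The segmentation networks: plain U-Net, its ablation variants, and the
full dilated multi-scale attention U-Net, plus a fuzzy c-means baseline.

All networks share one encoder–decoder skeleton.  Each encoder stage is
a feature block followed by 2x2 max pooling, doubling the channel width
per downsampling; the bridge applies one more block at the lowest
resolution.  Each decoder stage bilinearly upsamples, restores channels
with a 1x1 convolution, concatenates the (optionally attention-gated)
encoder skip features, and refines with another block.  A 1x1 convolution
and sigmoid head produce the per-pixel foreground probability.

The six ``variant`` names differ only in two switches — which feature
block is used (plain double 3x3 conv / classic multi-kernel Inception /
dilated multi-scale Inception) and whether skip connections pass through
the channel-attention gate:

========================  ====================  =========
variant                   block                 attention
========================  ====================  =========
unet                      plain                 no
unet_attn                 plain                 yes
unet_inception            inception (1/3/5)     no
unet_dilated_ms           dilated (r=1/2/3)     no
unet_inception_attn       inception (1/3/5)     yes
dmsaunet                  dilated (r=1/2/3)     yes
========================  ====================  =========
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .blocks import (
    AttentionParams,
    InceptionConfig,
    attention_graph,
    he_uniform,
    inception_graph,
    init_attention_params,
    init_inception_params,
)

__all__ = [
    "ModelConfig",
    "Model",
    "build_model",
    "count_parameters",
    "fcm_segment",
    "VARIANTS",
]

# variant -> (block kind, attention on skips)
VARIANTS: dict[str, tuple[str, bool]] = {
    "unet": ("plain", False),
    "unet_attn": ("plain", True),
    "unet_inception": ("inception", False),
    "unet_dilated_ms": ("dilated", False),
    "unet_inception_attn": ("inception", True),
    "dmsaunet": ("dilated", True),
}

_BLOCK_GEOMETRY = {
    # (branch kernels, branch rates) for the two Inception-style blocks
    "inception": ((1, 3, 5), (1, 1, 1)),
    "dilated": ((3, 3, 3), (1, 2, 3)),
}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``base_channels`` is the width of the first stage; widths double per
    downsampling and the bridge keeps the width of the deepest stage.
    ``input_size`` is (H, W, C) and H, W must be divisible by 2**depth.
    """

    variant: str = "dmsaunet"
    depth: int = 4
    base_channels: int = 64
    input_size: tuple[int, int, int] = (128, 128, 3)
    inception: InceptionConfig | None = None
    attention_reduction: int = 8
    threshold: float = 0.5

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}"
            )
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        h, w, c = self.input_size
        f = 2**self.depth
        if h % f or w % f:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2**depth = {f}"
            )
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def block_kind(self) -> str:
        return VARIANTS[self.variant][0]

    @property
    def use_attention(self) -> bool:
        return VARIANTS[self.variant][1]

    @property
    def stage_widths(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2**s for s in range(self.depth))

    @property
    def bridge_width(self) -> int:
        return self.base_channels * 2 ** (self.depth - 1)

    def stage_inception(self, out_channels: int) -> InceptionConfig:
        kernels, rates = _BLOCK_GEOMETRY[self.block_kind]
        base = self.inception or InceptionConfig(
            branch_rates=rates, branch_kernels=kernels
        )
        return base.resolve(out_channels)


def _largest_divisor_leq(c: int, cap: int) -> int:
    for d in range(min(cap, c), 0, -1):
        if c % d == 0:
            return d
    return 1


class Model:
    """A built network: parameter tensors plus a deterministic forward pass."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        self.params: dict[str, Tensor] = {}
        self._attention: dict[int, AttentionParams] = {}
        self._init_params(np.random.default_rng(self.seed))

    # -- construction --------------------------------------------------------
    def _add_conv(self, rng, name: str, k: int, cin: int, cout: int) -> None:
        self.params[f"{name}.w"] = Tensor(
            he_uniform(rng, (k, k, cin, cout), fan_in=k * k * cin), requires_grad=True
        )
        self.params[f"{name}.b"] = Tensor(np.zeros(cout), requires_grad=True)

    def _add_block(self, rng, name: str, cin: int, cout: int) -> None:
        if self.config.block_kind == "plain":
            self._add_conv(rng, f"{name}.conv1", 3, cin, cout)
            self._add_conv(rng, f"{name}.conv2", 3, cout, cout)
        else:
            cfg = self.config.stage_inception(cout)
            for key, t in init_inception_params(cfg, cin, rng).items():
                self.params[f"{name}.{key}"] = t

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        widths = cfg.stage_widths
        cin = cfg.input_size[2]
        for s, wdt in enumerate(widths):
            self._add_block(rng, f"enc{s}", cin, wdt)
            cin = wdt
        self._add_block(rng, "bridge", cin, cfg.bridge_width)
        cin = cfg.bridge_width
        for s in reversed(range(cfg.depth)):
            wdt = widths[s]
            self._add_conv(rng, f"dec{s}.up", 1, cin, wdt)
            if cfg.use_attention:
                rho = _largest_divisor_leq(wdt, cfg.attention_reduction)
                att = init_attention_params(wdt, rho, rng)
                self._attention[s] = att
                for leaf in ("fc1_w", "fc1_b", "fc2_w", "fc2_b"):
                    self.params[f"dec{s}.attn.{leaf}"] = getattr(att, leaf)
            self._add_block(rng, f"dec{s}.block", 2 * wdt, wdt)
            cin = wdt
        self._add_conv(rng, "head", 1, cin, 1)

    # -- forward -------------------------------------------------------------
    def _block(self, name: str, x: Tensor, cout: int) -> Tensor:
        if self.config.block_kind == "plain":
            x = T.relu(
                T.conv2d(x, self.params[f"{name}.conv1.w"], self.params[f"{name}.conv1.b"])
            )
            return T.relu(
                T.conv2d(x, self.params[f"{name}.conv2.w"], self.params[f"{name}.conv2.b"])
            )
        cfg = self.config.stage_inception(cout)
        sub = {
            k[len(name) + 1 :]: v
            for k, v in self.params.items()
            if k.startswith(name + ".")
        }
        return inception_graph(x, cfg, sub)

    def forward(self, images: np.ndarray | Tensor) -> Tensor:
        """Probability maps for a batch: (N, H, W, C) -> (N, H, W, 1) in (0, 1)."""
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, dtype=np.float64))
        if x.ndim == 3:
            x = Tensor(x.data[None])
        h, w, c = self.config.input_size
        if x.shape[1:] != (h, w, c):
            raise ValueError(
                f"expected input of shape (N, {h}, {w}, {c}), got {x.shape}"
            )
        cfg = self.config
        widths = cfg.stage_widths
        skips: list[Tensor] = []
        for s, wdt in enumerate(widths):
            x = self._block(f"enc{s}", x, wdt)
            skips.append(x)
            x = T.maxpool2x2(x)
        x = self._block("bridge", x, cfg.bridge_width)
        for s in reversed(range(cfg.depth)):
            skip = skips[s]
            x = T.upsample_bilinear(x, (skip.shape[1], skip.shape[2]))
            x = T.relu(
                T.conv2d(x, self.params[f"dec{s}.up.w"], self.params[f"dec{s}.up.b"])
            )
            if cfg.use_attention:
                skip, _ = attention_graph(skip, self._attention[s])
            x = T.concat([skip, x], axis=-1)
            x = self._block(f"dec{s}.block", x, widths[s])
        logits = T.conv2d(x, self.params["head.w"], self.params["head.b"])
        return T.sigmoid(logits)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Probability maps as a plain (N, H, W) array, no gradient tape."""
        images = np.asarray(images, dtype=np.float64)
        single = images.ndim == 3
        if single:
            images = images[None]
        out = self.forward(Tensor(images)).data[..., 0]
        return out[0] if single else out

    def predict_mask(self, images: np.ndarray, threshold: float | None = None) -> np.ndarray:
        thr = self.config.threshold if threshold is None else threshold
        return (self.predict(images) >= thr).astype(np.uint8)

    # -- bookkeeping ---------------------------------------------------------
    def count_parameters(self) -> int:
        return count_parameters(self.params)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in weights:
                raise KeyError(f"missing weight {k!r}")
            if weights[k].shape != v.data.shape:
                raise ValueError(
                    f"weight {k!r}: shape {weights[k].shape} != {v.data.shape}"
                )
            v.data = np.asarray(weights[k], dtype=np.float64).copy()


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Construct a seeded model; identical (config, seed) gives identical weights."""
    return Model(config, seed=seed)


def count_parameters(params) -> int:
    """Total trainable scalar count of a parameter dict or a Model."""
    if isinstance(params, Model):
        params = params.params
    return int(sum(v.data.size for v in params.values()))


# ---------------------------------------------------------------------------
# fuzzy c-means baseline
# ---------------------------------------------------------------------------

def fcm_segment(
    image: np.ndarray,
    clusters: int = 2,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 100,
    return_memberships: bool = False,
):
    """Classical fuzzy c-means segmentation of a single image.

    Features are the grayscale intensity and its 3x3 local mean.  The
    alternating membership/centroid updates run until the centroid shift
    drops below ``tol``.  The cluster whose intensity centroid lies
    farthest from the background mode (the histogram peak of intensity)
    is labelled foreground.

    Returns a binary H x W mask (and the membership array if requested).
    """
    from scipy.ndimage import uniform_filter

    if clusters < 2:
        raise ValueError("clusters must be >= 2")
    if fuzzifier <= 1.0:
        raise ValueError("fuzzifier must exceed 1")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        gray = img.mean(axis=2)
    elif img.ndim == 2:
        gray = img
    else:
        raise ValueError(f"image must be H x W or H x W x C, got shape {img.shape}")
    feats = np.stack(
        [gray.ravel(), uniform_filter(gray, size=3, mode="nearest").ravel()], axis=1
    )
    n = feats.shape[0]

    spread = float(gray.max() - gray.min())
    if spread < 1e-12:
        warnings.warn("constant image: degenerate clusters, empty foreground")
        mask = np.zeros(gray.shape, dtype=np.uint8)
        if return_memberships:
            return mask, np.full((n, clusters), 1.0 / clusters)
        return mask

    # deterministic centroid init: evenly spaced intensity quantiles
    qs = np.linspace(0.05, 0.95, clusters)
    centers = np.stack([np.quantile(feats, q, axis=0) for q in qs])

    expo = 2.0 / (fuzzifier - 1.0)
    u = np.full((n, clusters), 1.0 / clusters)
    converged = False
    for _ in range(max_iter):
        d2 = ((feats[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-expo / 2.0)
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u**fuzzifier
        new_centers = (um.T @ feats) / um.sum(axis=0)[:, None]
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fuzzy c-means did not converge in {max_iter} iterations; "
            "returning best-so-far partition"
        )

    hist, edges = np.histogram(gray, bins=64)
    background_mode = 0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1])
    fg_cluster = int(np.abs(centers[:, 0] - background_mode).argmax())
    labels = u.argmax(axis=1).reshape(gray.shape)
    mask = (labels == fg_cluster).astype(np.uint8)
    if return_memberships:
        return mask, u
    return mask
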