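"""Core tensor operators: dilated convolution, dilated Inception, attention.

These are the three computational units the segmentation network is built
from.  Each has a pure, array-in/array-out public form operating on a
single H x W x C feature map (the natural unit for unit testing and
inspection) plus a graph form (prefixed ``_graph``) used inside the
trainable network, where inputs and parameters are autodiff tensors.

Conventions: feature maps are rank-3 ``H x W x C`` float arrays; kernels
are ``k x k x C_in x C_out``; all convolutions use "same" padding and
stride 1, so spatial dimensions never change inside a block.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import _tensor as T
from ._tensor import Tensor

__all__ = [
    "ConvKernelSpec",
    "InceptionConfig",
    "AttentionParams",
    "classical_conv",
    "dilated_conv",
    "effective_kernel_size",
    "receptive_field_gain",
    "zero_inflate_kernel",
    "dilated_inception_forward",
    "init_inception_params",
    "attention_forward",
    "attention_weights",
    "init_attention_params",
    "he_uniform",
]


# ---------------------------------------------------------------------------
# receptive-field algebra
# ---------------------------------------------------------------------------

def effective_kernel_size(k: int, r: int) -> int:
    """Footprint of a k x k kernel dilated at rate r: ``k + (k-1)(r-1)``.

    Inserting ``r - 1`` zeros between adjacent taps spreads the k weights
    over a larger stencil without adding parameters; at ``r = 1`` the
    kernel is unchanged.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {k}")
    if r < 1:
        raise ValueError(f"dilation rate must be >= 1, got {r}")
    return k + (k - 1) * (r - 1)


def receptive_field_gain(k: int, r: int) -> float:
    """Areal growth factor of the receptive field, ``(k_s / k)**2``."""
    return (effective_kernel_size(k, r) / k) ** 2


def zero_inflate_kernel(w: np.ndarray, rate: int) -> np.ndarray:
    """Materialise the sparse ``k_s x k_s`` kernel equivalent to dilation.

    Places the taps of ``w`` (k, k, ...) on a zero grid with ``rate - 1``
    zeros between them.  A classical convolution with the inflated kernel
    equals a dilated convolution with the original one — the identity the
    test suite uses as an oracle.
    """
    if rate < 1:
        raise ValueError(f"dilation rate must be >= 1, got {rate}")
    k = w.shape[0]
    ks = effective_kernel_size(k, rate)
    out = np.zeros((ks, ks) + w.shape[2:], dtype=w.dtype)
    out[::rate, ::rate] = w
    return out


# ---------------------------------------------------------------------------
# convolution operators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvKernelSpec:
    """Geometry of a convolution kernel: odd edge ``k``, dilation ``rate``.

    Padding is always "same" and stride 1; the trainable weight count per
    (in-channel, out-channel) pair is ``k**2`` at every rate.
    """

    k: int
    rate: int = 1
    padding: str = "same"
    stride: int = 1

    def __post_init__(self):
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"kernel edge must be odd and >= 1, got {self.k}")
        if self.rate < 1:
            raise ValueError(f"dilation rate must be >= 1, got {self.rate}")
        if self.padding != "same" or self.stride != 1:
            raise ValueError("only same-padding, stride-1 convolutions are supported")

    @property
    def effective_size(self) -> int:
        return effective_kernel_size(self.k, self.rate)


def _as_map(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise ValueError(f"feature map must be H x W x C, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("feature map contains non-finite entries")
    return image


def _as_kernel(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim == 2:
        w = w[:, :, None, None]
    if w.ndim != 4 or w.shape[0] != w.shape[1]:
        raise ValueError(f"kernel must be k x k x Cin x Cout, got shape {w.shape}")
    if w.shape[0] % 2 == 0:
        raise ValueError(f"kernel edge must be odd, got {w.shape[0]}")
    return w


def classical_conv(
    image: np.ndarray, weights: np.ndarray, bias: np.ndarray | None = None
) -> np.ndarray:
    """Standard same-padding convolution of an H x W x C map.

    Computes ``y(p) = sum_i x[p + i] * w[i]`` over the kernel stencil
    centred at each pixel, linearly in both arguments.
    """
    return dilated_conv(image, weights, rate=1, bias=bias)


def dilated_conv(
    image: np.ndarray,
    weights: np.ndarray,
    rate: int,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Dilated (atrous) convolution: taps sample at offsets ``rate * i``.

    The weight count is independent of ``rate``; only the stencil spacing
    grows.  At ``rate = 1`` this is exactly :func:`classical_conv`.
    """
    img = _as_map(image)
    w = _as_kernel(weights)
    if img.shape[2] != w.shape[2]:
        raise ValueError(
            f"image has {img.shape[2]} channels but kernel expects {w.shape[2]}"
        )
    b = None if bias is None else Tensor(np.asarray(bias, dtype=np.float64))
    out = T.conv2d(Tensor(img[None]), Tensor(w), b, rate=rate)
    return out.data[0]


# ---------------------------------------------------------------------------
# dilated Inception block
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InceptionConfig:
    """Multi-branch block: three bottlenecked conv branches + global context.

    Each branch is a 1x1 channel reduction to ``bottleneck_channels``
    followed by a ``branch_kernels[i]`` convolution dilated at
    ``branch_rates[i]``.  A fourth path global-average-pools the input,
    applies a 1x1 convolution and bilinearly upsamples back — injecting
    image-level context.  All paths (plus the raw input, when
    ``use_residual``) are concatenated along channels and fused by a 1x1
    convolution to ``out_channels``.  An additive fusion mode sums the
    paths instead of concatenating.

    The three branch footprints (effective kernel sizes) must be strictly
    increasing so the branches genuinely cover multiple scales: dilated
    3x3 branches at rates (1, 2, 3) give footprints 3/5/7, while classic
    multi-kernel branches (1, 3, 5) at rate 1 give footprints 1/3/5.
    """

    branch_rates: tuple[int, int, int] = (1, 2, 3)
    branch_kernels: tuple[int, int, int] = (3, 3, 3)
    bottleneck_channels: int | None = None  # default: out_channels // 4, min 1
    out_channels: int | None = None  # default: set by the enclosing model
    use_residual: bool = True
    fusion: str = "concat"  # "concat" | "add"

    def __post_init__(self):
        if len(self.branch_rates) != 3 or len(self.branch_kernels) != 3:
            raise ValueError("the block has exactly three conv branches")
        if any(r < 1 for r in self.branch_rates):
            raise ValueError(f"branch rates must be >= 1, got {self.branch_rates}")
        sizes = [
            effective_kernel_size(k, r)
            for k, r in zip(self.branch_kernels, self.branch_rates)
        ]
        if not (sizes[0] < sizes[1] < sizes[2]):
            raise ValueError(
                f"branch footprints must be strictly increasing, got {sizes}"
            )
        if self.fusion not in ("concat", "add"):
            raise ValueError(f"fusion must be 'concat' or 'add', got {self.fusion!r}")

    def resolve(self, out_channels: int) -> "InceptionConfig":
        """Fill in the channel widths for a concrete stage."""
        bott = self.bottleneck_channels or max(1, out_channels // 4)
        return dataclasses.replace(
            self, bottleneck_channels=bott, out_channels=out_channels
        )


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = math.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape)


def init_inception_params(
    config: InceptionConfig, in_channels: int, rng: np.random.Generator
) -> dict[str, Tensor]:
    """He-uniform conv weights, zero biases, for one dilated Inception block."""
    if config.out_channels is None:
        raise ValueError("InceptionConfig must be resolved (out_channels set)")
    cfg = config.resolve(config.out_channels)
    b, co = cfg.bottleneck_channels, cfg.out_channels
    p: dict[str, Tensor] = {}

    def conv_param(name, k, cin, cout):
        p[f"{name}.w"] = Tensor(
            he_uniform(rng, (k, k, cin, cout), fan_in=k * k * cin), requires_grad=True
        )
        p[f"{name}.b"] = Tensor(np.zeros(cout), requires_grad=True)

    for i, kk in enumerate(cfg.branch_kernels):
        conv_param(f"branch{i}.reduce", 1, in_channels, b)
        conv_param(f"branch{i}.conv", kk, b, b)
    conv_param("gap.conv", 1, in_channels, b)
    if cfg.fusion == "concat":
        fused_in = 4 * b + (in_channels if cfg.use_residual else 0)
    else:
        fused_in = b
        if cfg.use_residual:
            conv_param("residual.project", 1, in_channels, b)
    conv_param("fuse", 1, fused_in, co)
    return p


def inception_graph(
    x: Tensor, config: InceptionConfig, params: Mapping[str, Tensor]
) -> Tensor:
    """Autodiff form of the block on an NHWC tensor."""
    parts = _inception_paths(x, config, params)
    return parts["fused"]


def _inception_paths(
    x: Tensor, config: InceptionConfig, params: Mapping[str, Tensor]
) -> dict[str, Tensor]:
    n, h, w, cin = x.shape
    expected = params["branch0.reduce.w"].shape[2]
    if cin != expected:
        raise ValueError(f"block expects {expected} input channels, got {cin}")
    parts: dict[str, Tensor] = {}
    branches: list[Tensor] = []
    for i, (kk, rate) in enumerate(zip(config.branch_kernels, config.branch_rates)):
        z = T.relu(
            T.conv2d(x, params[f"branch{i}.reduce.w"], params[f"branch{i}.reduce.b"])
        )
        z = T.relu(T.conv2d(z, params[f"branch{i}.conv.w"], params[f"branch{i}.conv.b"], rate=rate))
        parts[f"G_{i + 1}"] = z
        branches.append(z)
    pooled = T.global_avg_pool(x)
    ctx = T.relu(T.conv2d(pooled, params["gap.conv.w"], params["gap.conv.b"]))
    gap = T.upsample_bilinear(ctx, (h, w))
    parts["G_gap"] = gap
    if config.fusion == "concat":
        pieces = branches + [gap]
        if config.use_residual:
            pieces.append(x)
        merged = T.concat(pieces, axis=-1)
    else:
        merged = branches[0] + branches[1] + branches[2] + gap
        if config.use_residual:
            merged = merged + T.conv2d(
                x, params["residual.project.w"], params["residual.project.b"]
            )
    fused = T.relu(T.conv2d(merged, params["fuse.w"], params["fuse.b"]))
    parts["fused"] = fused
    return parts


def dilated_inception_forward(
    g_or: np.ndarray,
    config: InceptionConfig,
    params: Mapping[str, Tensor | np.ndarray],
    return_parts: bool = False,
):
    """Run one dilated Inception block on a single H x W x C feature map.

    With ``return_parts=True`` also returns the intermediate branch
    outputs ``G_1..G_3`` and the global-context map ``G_gap`` — useful
    for inspecting what each scale responds to.
    """
    img = _as_map(g_or)
    tp = {k: (v if isinstance(v, Tensor) else Tensor(v)) for k, v in params.items()}
    parts = _inception_paths(Tensor(img[None]), config, tp)
    out = parts["fused"].data[0]
    if return_parts:
        return out, {k: v.data[0] for k, v in parts.items() if k != "fused"}
    return out


# ---------------------------------------------------------------------------
# channel attention gate
# ---------------------------------------------------------------------------

@dataclass
class AttentionParams:
    """Shared two-layer bottleneck MLP of a channel-attention gate.

    ``fc1`` maps C channels to C / reduction hidden units, ``fc2`` maps
    back to C.  The same weights serve both the global-max-pool and the
    global-average-pool branch.
    """

    fc1_w: Tensor
    fc1_b: Tensor
    fc2_w: Tensor
    fc2_b: Tensor
    reduction: int

    @property
    def channels(self) -> int:
        return self.fc1_w.shape[0]


def init_attention_params(
    channels: int, reduction: int, rng: np.random.Generator
) -> AttentionParams:
    if reduction < 1 or channels % reduction != 0:
        raise ValueError(
            f"reduction {reduction} must be a positive divisor of {channels} channels"
        )
    hidden = channels // reduction
    return AttentionParams(
        fc1_w=Tensor(he_uniform(rng, (channels, hidden), channels), requires_grad=True),
        fc1_b=Tensor(np.zeros(hidden), requires_grad=True),
        fc2_w=Tensor(he_uniform(rng, (hidden, channels), hidden), requires_grad=True),
        fc2_b=Tensor(np.zeros(channels), requires_grad=True),
        reduction=reduction,
    )


def attention_graph(x: Tensor, params: AttentionParams) -> tuple[Tensor, Tensor]:
    """Channel gate on an NHWC tensor; returns (gated map, weights S_a).

    Per-channel global max and mean descriptors each pass through the
    shared Fc2(ReLU(Fc1(.))) stack; the branch outputs are summed and a
    sigmoid squashes them into per-channel weights in (0, 1), which then
    rescale every spatial position of the input.
    """
    n = x.shape[0]
    c = x.shape[3]
    if params.channels != c:
        raise ValueError(f"attention sized for {params.channels} channels, input has {c}")

    def excite(descriptor: Tensor) -> Tensor:
        flat = _reshape(descriptor, (n, c))
        hidden = T.relu(T.dense(flat, params.fc1_w, params.fc1_b))
        return T.dense(hidden, params.fc2_w, params.fc2_b)

    gmp = excite(T.global_max_pool(x))
    gap = excite(T.global_avg_pool(x))
    s_a = T.sigmoid(gmp + gap)
    gated = x * _reshape(s_a, (n, 1, 1, c))
    return gated, s_a


def _reshape(t: Tensor, shape: tuple[int, ...]) -> Tensor:
    data = t.data.reshape(shape)

    def backward(g):
        t._accumulate(g.reshape(t.data.shape))

    return T._make(data, (t,), backward)


def attention_forward(g: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Apply the channel-attention gate to a single H x W x C map."""
    img = _as_map(g)
    gated, _ = attention_graph(Tensor(img[None]), params)
    return gated.data[0]


def attention_weights(g: np.ndarray, params: AttentionParams) -> np.ndarray:
    """The per-channel gate weights S_a in (0, 1) for a single map."""
    img = _as_map(g)
    _, s_a = attention_graph(Tensor(img[None]), params)
    return s_a.data[0]
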