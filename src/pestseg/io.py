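"""Image / mask / manifest / checkpoint I/O.

Conventions: images load as H x W x 3 floats in [0, 1], resized by
bilinear interpolation when a target size is given; masks load as
{0, 1} uint8 (8-bit values thresholded at 128) and are resized by
nearest-neighbour so they stay binary.  Masks are written as 8-bit
single-channel PNGs with values {0, 255}, foreground = pest = 255.
Row-major, origin top-left, 0-based indexing throughout.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .model import Model, ModelConfig

__all__ = [
    "read_image",
    "read_mask",
    "write_mask",
    "read_manifest",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


def _load_array(path) -> np.ndarray:
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such image file: {p}")
    try:
        arr = iio.imread(p)
    except Exception as e:
        raise IOError(f"cannot read image {p}: {e}") from e
    return np.asarray(arr)


def read_image(path, size: tuple[int, int] | None = None) -> np.ndarray:
    """Load an RGB image as H x W x 3 in [0, 1], optionally resized (bilinear)."""
    from skimage.transform import resize

    arr = _load_array(path)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    img = arr.astype(np.float64)
    if np.issubdtype(arr.dtype, np.integer):
        img = img / np.iinfo(arr.dtype).max
    if size is not None and img.shape[:2] != tuple(size):
        img = resize(img, size, order=1, anti_aliasing=False, preserve_range=True)
    return np.clip(img, 0.0, 1.0)


def read_mask(path, size: tuple[int, int] | None = None) -> np.ndarray:
    """Load a binary mask as {0, 1} uint8; 8-bit values >= 128 are foreground.

    Resizing uses nearest-neighbour interpolation, which cannot create
    values outside the original binary set.
    """
    from skimage.transform import resize

    arr = _load_array(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    mask = (arr >= 128).astype(np.uint8) if np.issubdtype(arr.dtype, np.integer) else (
        arr >= 0.5
    ).astype(np.uint8)
    if size is not None and mask.shape != tuple(size):
        mask = resize(mask, size, order=0, anti_aliasing=False, preserve_range=True)
        mask = mask.astype(np.uint8)
    return mask


def write_mask(path, mask: np.ndarray) -> None:
    """Write a {0, 1} mask as an 8-bit PNG with values {0, 255}."""
    m = np.asarray(mask)
    if not np.all(np.isin(np.unique(m), (0, 1))):
        raise ValueError("mask must be binary {0, 1}")
    iio.imwrite(Path(path), (m.astype(np.uint8) * 255))


def read_manifest(path, size: tuple[int, int] | None = None) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Load all image/mask pairs listed in a CSV manifest.

    Paths are resolved relative to the manifest's directory.  Duplicate
    image paths and missing files are rejected.
    """
    p = Path(path)
    df = pd.read_csv(p)
    for col in ("image_path", "mask_path"):
        if col not in df.columns:
            raise ValueError(f"manifest {p} lacks required column {col!r}")
    if df["image_path"].duplicated().any():
        dupes = df.loc[df["image_path"].duplicated(), "image_path"].tolist()
        raise ValueError(f"manifest has duplicate image paths: {dupes[:5]}")
    root = p.parent
    images, masks = [], []
    for _, row in df.iterrows():
        images.append(read_image(root / row["image_path"], size=size))
        masks.append(read_mask(root / row["mask_path"], size=size))
    return np.stack(images), np.stack(masks), df


def save_checkpoint(path, model: Model) -> None:
    """Single-file archive of weights + config + seed (npz, versioned)."""
    import dataclasses
    import json

    cfg = model.config
    meta = dataclasses.asdict(cfg)
    if cfg.inception is not None:
        meta["inception"] = dataclasses.asdict(cfg.inception)
    payload = {
        "__meta__": np.frombuffer(
            json.dumps(
                {"format_version": CHECKPOINT_FORMAT_VERSION, "config": meta, "seed": model.seed}
            ).encode(),
            dtype=np.uint8,
        )
    }
    payload.update({f"param:{k}": v.data for k, v in model.params.items()})
    np.savez(Path(path), **payload)


def load_checkpoint(path) -> Model:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    import json

    from .blocks import InceptionConfig

    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format version {meta.get('format_version')}"
            )
        cfg_dict = dict(meta["config"])
        if cfg_dict.get("inception") is not None:
            inc = dict(cfg_dict["inception"])
            inc["branch_rates"] = tuple(inc["branch_rates"])
            inc["branch_kernels"] = tuple(inc["branch_kernels"])
            cfg_dict["inception"] = InceptionConfig(**inc)
        cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
        cfg = ModelConfig(**cfg_dict)
        model = Model(cfg, seed=int(meta["seed"]))
        weights = {k[len("param:") :]: z[k] for k in z.files if k.startswith("param:")}
    model.set_weights(weights)
    return model
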