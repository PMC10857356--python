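"""Deterministic slice preparation and stochastic training augmentation.

Covers the three preprocessing stages the segmentation models rely on:

* a fixed center crop (default 87.5% of each side) that removes the empty
  CT border before the slice enters the network;
* 2.5D stack construction — the k slices centred on the target slice are
  stacked as input channels (k in {1, 3, 5}); k=1 is exactly the plain 2D
  pathway.  Positions past the volume ends are filled by edge replication
  by default (configurable to zero fill);
* a seeded augmentation pipeline applied with global probability p during
  training: horizontal flip, small rotation, scaling, brightness/contrast
  jitter and additive noise.  Geometric transforms are applied identically
  to image and mask; intensity transforms touch the image only; masks are
  warped with nearest-neighbour interpolation so they stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume

__all__ = [
    "SliceStack",
    "center_crop",
    "build_stack",
    "stack_channels",
    "augment",
    "DEFAULT_TRANSFORMS",
    "DEFAULT_CROP_FRACTION",
]

#: border crop retained by default ("up to 87.5%" is applied as a fixed value)
DEFAULT_CROP_FRACTION = 0.875

#: the default "strong" augmentation pipeline; each entry is individually
#: removable/overridable in run configs
DEFAULT_TRANSFORMS: tuple[dict, ...] = (
    {"name": "hflip"},
    {"name": "rotate", "limit_deg": 15.0},
    {"name": "scale", "limit": 0.10},
    {"name": "brightness_contrast", "limit": 0.20},
    {"name": "gauss_noise", "sd": 0.02},
)


@dataclass
class SliceStack:
    """k adjacent slices as channels, centred on the prediction target."""

    channels: np.ndarray  # (k, rows, cols), ordered by slice index
    center_index: int
    crop_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3:
            raise ValueError("channels must be (k, rows, cols)")
        if self.channels.shape[0] % 2 == 0:
            raise ValueError("k must be odd")

    @property
    def k(self) -> int:
        return self.channels.shape[0]

    @property
    def center(self) -> np.ndarray:
        return self.channels[self.k // 2]


def center_crop(image: np.ndarray, fraction: float) -> np.ndarray:
    """Retain the central ``fraction`` of each side of a 2-D image.

    Output side lengths are ``round(fraction * side)``.  For stacks, apply
    with identical fraction per channel (the window is position-only, so a
    paired mask crops to the identical region).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"crop fraction must be in (0, 1], got {fraction}")
    image = np.asarray(image)
    h, w = image.shape[-2:]
    oh, ow = int(round(fraction * h)), int(round(fraction * w))
    r0, c0 = (h - oh) // 2, (w - ow) // 2
    return image[..., r0 : r0 + oh, c0 : c0 + ow]


def stack_channels(voxels: np.ndarray, index: int, k: int, boundary: str = "edge") -> np.ndarray:
    """Return the (k, rows, cols) channel array for one center slice."""
    if k not in (1, 3, 5):
        raise ValueError(f"k must be one of 1, 3, 5, got {k}")
    n = voxels.shape[0]
    if not 0 <= index < n:
        raise IndexError(f"slice index {index} out of range for {n} slices")
    half = k // 2
    idx = np.arange(index - half, index + half + 1)
    if boundary == "edge":
        idx = np.clip(idx, 0, n - 1)
        return voxels[idx]
    elif boundary == "zero":
        out = np.zeros((k,) + voxels.shape[1:], dtype=voxels.dtype)
        for j, i in enumerate(idx):
            if 0 <= i < n:
                out[j] = voxels[i]
        return out
    raise ValueError(f"boundary must be 'edge' or 'zero', got {boundary!r}")


def build_stack(volume: CTVolume, index: int, k: int, boundary: str = "edge") -> SliceStack:
    """Build the 2.5D input stack centred on slice ``index``.

    Out-of-range positions are filled by edge replication (nearest existing
    slice) by default.  ``k=1`` degenerates to the single target slice — the
    plain 2D pathway.
    """
    return SliceStack(stack_channels(volume.voxels, index, k, boundary), center_index=index)


# ---------------------------------------------------------------------------
# augmentation


def _sample_params(rng: np.random.Generator, transforms) -> list[tuple[str, dict]]:
    ops = []
    for t in transforms:
        name = t["name"]
        if name == "hflip":
            ops.append(("hflip", {}))
        elif name == "rotate":
            lim = float(t.get("limit_deg", 15.0))
            ops.append(("rotate", {"angle": float(rng.uniform(-lim, lim))}))
        elif name == "scale":
            lim = float(t.get("limit", 0.1))
            ops.append(("scale", {"factor": float(1.0 + rng.uniform(-lim, lim))}))
        elif name == "brightness_contrast":
            lim = float(t.get("limit", 0.2))
            ops.append(
                (
                    "brightness_contrast",
                    {
                        "contrast": float(1.0 + rng.uniform(-lim, lim)),
                        "brightness": float(rng.uniform(-lim, lim)),
                    },
                )
            )
        elif name == "gauss_noise":
            ops.append(("gauss_noise", {"sd": float(t.get("sd", 0.02))}))
        else:
            raise ValueError(f"unknown transform {name!r}")
    return ops


def _warp_geometric(plane: np.ndarray, name: str, p: dict, order: int) -> np.ndarray:
    if name == "hflip":
        return plane[..., ::-1].copy()
    if name == "rotate":
        return ndimage.rotate(plane, p["angle"], reshape=False, order=order, mode="nearest")
    if name == "scale":
        s = p["factor"]
        center = (np.asarray(plane.shape) - 1) / 2
        matrix = np.diag([1.0 / s, 1.0 / s])
        offset = center - matrix @ center
        return ndimage.affine_transform(plane, matrix, offset=offset, order=order, mode="nearest")
    raise AssertionError(name)


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    p: float,
    seed: int | np.random.Generator,
    transforms=DEFAULT_TRANSFORMS,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the augmentation pipeline with global probability ``p``.

    ``image`` may be a single 2-D slice or a (k, rows, cols) channel stack;
    every channel receives the same geometric transform.  ``mask`` is a 2-D
    binary grid.  The same ``(image, mask, p, seed)`` always produces the
    same output.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[-2:] != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} are not congruent")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rng.random() >= p:
        return image.copy(), mask.copy()

    ops = _sample_params(rng, transforms)
    ftype = image.dtype if np.issubdtype(image.dtype, np.floating) else np.float32
    img = image.astype(ftype, copy=True)
    msk = mask.astype(np.uint8, copy=True)
    for name, prm in ops:
        if name in ("hflip", "rotate", "scale"):
            if img.ndim == 3:
                img = np.stack([_warp_geometric(ch, name, prm, order=1) for ch in img])
            else:
                img = _warp_geometric(img, name, prm, order=1)
            msk = _warp_geometric(msk, name, prm, order=0)
        elif name == "brightness_contrast":
            img = img * prm["contrast"] + prm["brightness"]
        elif name == "gauss_noise":
            img = img + rng.normal(0.0, prm["sd"], size=img.shape).astype(img.dtype)
    return img, (msk > 0).astype(np.uint8)
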