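"""Probability maps and binary masks from trained models.

Two usage scenarios are implemented.  In the mirrored-averaging scenario a
slice (or slice stack) is predicted twice — once as-is and once left-right
mirrored — and the two probability maps are averaged after mirroring the
second back::

    tta(f, x) = ( f(x) + mirror(f(mirror(x))) ) / 2

Probabilities are averaged *before* thresholding, which is the only order
under which threshold sweeps remain well defined.  In the stacked 2.5D
scenario each slice is predicted independently from its k-channel stack.
By default mirrored averaging is on for the 2D pathway (k=1) and off for
k>1, matching the two scenario descriptions; both are switchable.

A "model" here is anything callable on a (k, rows, cols) channel array
returning a (rows, cols) foreground probability map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SliceStack, build_stack, center_crop
from .volume_io import CTVolume, MaskVolume, normalize_intensity

__all__ = ["ProbabilityVolume", "predict_slice_tta", "predict_volume", "binarize",
           "segment_series"]


@dataclass
class ProbabilityVolume:
    """Per-voxel foreground probabilities congruent to the input CT volume."""

    values: np.ndarray  # (slice, row, col), in [0, 1]
    pixel_spacing: tuple[float, float]
    slice_spacing: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (slice, row, col)")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"probabilities must lie in [0, 1], got range [{lo}, {hi}]")

    @property
    def shape(self):
        return self.values.shape


def _mirror(a: np.ndarray) -> np.ndarray:
    # left-right reflection = column reversal, applied to every channel
    return np.ascontiguousarray(a[..., ::-1])


def predict_slice_tta(model, stack: SliceStack | np.ndarray) -> np.ndarray:
    """Mirror-averaged prediction for one slice stack.

    Returns ``(f(x) + mirror(f(mirror(x)))) / 2`` with left-right mirroring
    applied to every channel.  Output shape equals the channel shape.
    """
    channels = stack.channels if isinstance(stack, SliceStack) else np.asarray(stack)
    expected = getattr(getattr(model, "config", None), "in_channels", None)
    if expected is not None and channels.ndim == 3 and channels.shape[0] != expected:
        raise ValueError(f"model expects {expected} channels, got {channels.shape[0]}")
    direct = np.asarray(model(channels))
    mirrored = np.asarray(model(_mirror(channels)))
    out = 0.5 * (direct + _mirror(mirrored))
    if out.shape != channels.shape[-2:]:
        raise ValueError(f"model output shape {out.shape} != slice shape {channels.shape[-2:]}")
    return out


def predict_volume(
    model,
    volume: CTVolume,
    k: int,
    use_tta: bool | None = None,
    crop_fraction: float = 1.0,
    boundary: str = "edge",
    pad_back: bool = True,
) -> ProbabilityVolume:
    """Predict the foreground probability for every slice of a volume.

    For each slice index the k-channel stack is built (edge replication at
    the volume ends), center-cropped by ``crop_fraction``, and predicted —
    mirror-averaged when ``use_tta`` (default: only for k=1).  Planes are
    independent, so evaluation order is irrelevant.  When the input was
    cropped and ``pad_back`` is set, each predicted plane is zero-padded
    back to the full slice shape so the output aligns with the input
    geometry.
    """
    if use_tta is None:
        use_tta = k == 1
    n, rows, cols = volume.shape
    planes = []
    for i in range(n):
        stack = build_stack(volume, i, k, boundary)
        channels = stack.channels
        if crop_fraction < 1:
            channels = center_crop(channels, crop_fraction)
        if use_tta:
            planes.append(predict_slice_tta(model, channels))
        else:
            planes.append(np.asarray(model(channels)))
    arr = np.stack(planes).astype(np.float32)
    if pad_back and arr.shape[1:] != (rows, cols):
        out = np.zeros((n, rows, cols), dtype=np.float32)
        r0 = (rows - arr.shape[1]) // 2
        c0 = (cols - arr.shape[2]) // 2
        out[:, r0 : r0 + arr.shape[1], c0 : c0 + arr.shape[2]] = arr
        arr = out
    return ProbabilityVolume(arr, volume.pixel_spacing, volume.slice_spacing)


def binarize(prob: ProbabilityVolume, threshold: float) -> MaskVolume:
    """Threshold a probability volume; a voxel exactly at the threshold is foreground."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return MaskVolume(
        (prob.values >= threshold).astype(np.uint8), prob.pixel_spacing, prob.slice_spacing
    )


def segment_series(
    model,
    volume: CTVolume,
    k: int,
    threshold: float = 0.5,
    use_tta: bool | None = None,
    crop_fraction: float = 1.0,
    normalize: bool = True,
    window: tuple[float, float] | None = None,
) -> tuple[ProbabilityVolume, MaskVolume]:
    """One-call pipeline: normalize (optionally windowed), predict, binarize."""
    lo, hi = window if window is not None else (None, None)
    vol = normalize_intensity(volume, lo, hi) if normalize else volume
    prob = predict_volume(model, vol, k=k, use_tta=use_tta, crop_fraction=crop_fraction)
    return prob, binarize(prob, threshold)
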