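"""U-Net architecture, Dice loss, and the training procedure.

The network is the classic encoder-decoder with skip connections: double
3x3 convolution blocks with relu activations, 2x2 max pooling on the way
down, nearest-neighbour upsampling + convolution + skip concatenation on
the way up, and a final 1x1 projection to two class maps under a softmax
(background / hematoma).  The foreground softmax channel is "the"
probability map used downstream.

Training follows the published recipe: Dice loss on the foreground
channel, Adam with learning rate 1e-4 and weight decay 1e-3, an
exponential per-epoch learning-rate schedule with factor 0.96, 40 epochs,
and augmentation applied with probability 0.4.  All of it runs on the CPU
with the numpy layers in :mod:`crescentseg._layers`; identical seeds and
configs give bit-identical histories.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._layers import Adam, Conv2d, DoubleConv, MaxPool2, ReLU, Upsample2
from .preprocess import (
    DEFAULT_CROP_FRACTION,
    DEFAULT_TRANSFORMS,
    augment,
    center_crop,
    stack_channels,
)
from .volume_io import normalize_intensity

__all__ = ["ModelConfig", "TrainConfig", "UNet", "build_unet", "dice_loss", "train",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``in_channels`` is the 2.5D stack size k (1, 3 or 5).  ``depth`` is the
    number of pooling levels; input sides must be divisible by 2**depth.
    Only the "simple" double-conv encoder is available; a pretrained
    efficientnet-b4 backbone would require downloaded weights and is not
    provided.
    """

    in_channels: int = 3
    out_channels: int = 2
    depth: int = 3
    base_filters: int = 16
    encoder: str = "simple"

    def validate(self) -> None:
        if self.in_channels not in (1, 3, 5):
            raise ValueError("ModelConfig.in_channels must be 1, 3 or 5")
        if self.out_channels != 2:
            raise ValueError("ModelConfig.out_channels must be 2 (softmax class maps)")
        if self.depth < 2:
            raise ValueError("ModelConfig.depth must be >= 2")
        if self.base_filters < 4:
            raise ValueError("ModelConfig.base_filters must be >= 4")
        if self.encoder != "simple":
            raise NotImplementedError(
                "only the 'simple' encoder is available; 'efficientnet-b4' needs "
                "pretrained weights and is out of scope"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the published recipe)."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-3
    epochs: int = 40
    lr_gamma: float = 0.96
    augment_p: float = 0.4
    batch_size: int = 8
    seed: int = 0
    smooth: float = 1.0
    crop_fraction: float = DEFAULT_CROP_FRACTION
    stack_boundary: str = "edge"
    early_stop_patience: int | None = None
    #: optional (low, high) grayscale window applied before [0,1] scaling;
    #: None uses each volume's own [min, max].  A soft-tissue window keeps
    #: the bright skull from compressing the brain/collection contrast.
    window: tuple[float, float] | None = None
    #: optional positive/negative slice balancing: keep at most this many
    #: hematoma-free slices per hematoma-bearing slice (None keeps all).
    #: Pure-Dice training is easily dragged into the all-background optimum
    #: when empty slices dominate the sampling.
    empty_slice_fraction: float | None = None

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("TrainConfig.learning_rate must be > 0")
        if not 0 < self.lr_gamma <= 1:
            raise ValueError("TrainConfig.lr_gamma must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("TrainConfig.epochs must be >= 1")
        if not 0 <= self.augment_p <= 1:
            raise ValueError("TrainConfig.augment_p must be in [0, 1]")
        if self.batch_size < 1:
            raise ValueError("TrainConfig.batch_size must be >= 1")
        if self.smooth <= 0:
            raise ValueError("TrainConfig.smooth must be > 0")


class UNet:
    """Encoder-decoder segmentation network with softmax output.

    Calling the model on a (k, H, W) channel stack returns the (H, W)
    foreground probability map; :meth:`forward` exposes the full batched
    (B, 2, H, W) softmax output.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        d, f0 = config.depth, config.base_filters
        filters = [f0 * 2**i for i in range(d + 1)]

        self.enc = []
        cin = config.in_channels
        for i in range(d):
            self.enc.append(DoubleConv(cin, filters[i], rng))
            cin = filters[i]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = DoubleConv(filters[d - 1], filters[d], rng)
        self.ups = [Upsample2() for _ in range(d)]
        self.upconvs = [Conv2d(filters[i + 1], filters[i], 3, rng) for i in range(d)]
        self.uprelus = [ReLU() for _ in range(d)]
        self.dec = [DoubleConv(2 * filters[i], filters[i], rng) for i in range(d)]
        self.head = Conv2d(filters[0], config.out_channels, 1, rng)

    # -- parameters -------------------------------------------------------
    def parameters(self):
        ps = []
        for blk in self.enc + [self.bottleneck] + self.upconvs + self.dec + [self.head]:
            ps += blk.params()
        return ps

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def checksum(self) -> float:
        return float(sum(np.abs(p.value).sum() for p in self.parameters()))

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4:
            raise ValueError("forward expects (batch, channels, rows, cols)")
        H, W = x.shape[2], x.shape[3]
        div = 2**self.config.depth
        if H % div or W % div:
            raise ValueError(
                f"input sides ({H}, {W}) must be divisible by 2**depth = {div}"
            )
        skips = []
        h = x
        for i in range(self.config.depth):
            h = self.enc[i].forward(h)
            skips.append(h)
            h = self.pools[i].forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = [s.shape[1] for s in skips]
        for i in reversed(range(self.config.depth)):
            h = self.ups[i].forward(h)
            h = self.uprelus[i].forward(self.upconvs[i].forward(h))
            h = np.concatenate([skips[i], h], axis=1)
            h = self.dec[i].forward(h)
        logits = self.head.forward(h)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        p = self._probs
        dz = p * (dprobs - (dprobs * p).sum(axis=1, keepdims=True))
        dh = self.head.backward(dz.astype(np.float32))
        dskips = [None] * self.config.depth
        for i in range(self.config.depth):
            dh = self.dec[i].backward(dh)
            cs = self._skip_channels[i]
            dskips[i], dup = dh[:, :cs], dh[:, cs:]
            dup = self.upconvs[i].backward(self.uprelus[i].backward(dup))
            dh = self.ups[i].backward(dup)
        dh = self.bottleneck.backward(dh)
        for i in reversed(range(self.config.depth)):
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[i]
            dh = self.enc[i].backward(dh)

    # -- convenience -------------------------------------------------------
    def __call__(self, channels: np.ndarray) -> np.ndarray:
        channels = np.asarray(channels, dtype=np.float32)
        if channels.ndim == 2:
            channels = channels[None]
        if channels.shape[0] != self.config.in_channels:
            raise ValueError(
                f"model expects {self.config.in_channels} channels, got {channels.shape[0]}"
            )
        return self.forward(channels[None])[0, 1]


def build_unet(config: ModelConfig, seed: int = 0) -> UNet:
    """Construct a seeded U-Net; identical (config, seed) give identical weights."""
    return UNet(config, seed=seed)


# ---------------------------------------------------------------------------
# loss


def dice_loss(pred_fg: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Dice loss ``1 - (2 sum(p t) + s) / (sum p + sum t + s)``.

    ``pred_fg`` is the foreground probability map, ``target`` the binary
    ground truth; ``smooth`` > 0 keeps the ratio defined on empty masks.
    """
    pred_fg = np.asarray(pred_fg, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred_fg.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred_fg.shape} vs {target.shape}")
    if smooth <= 0:
        raise ValueError("smooth must be > 0")
    num = 2.0 * (pred_fg * target).sum() + smooth
    den = pred_fg.sum() + target.sum() + smooth
    return float(1.0 - num / den)


def _dice_loss_and_grad(probs: np.ndarray, targets: np.ndarray, smooth: float):
    """Batch-global soft Dice loss and its gradient wrt the softmax output.

    The batch is scored as one large foreground map (a per-sample mean would
    hand most of the gradient to slices with no hematoma, which destabilises
    pure-Dice training on lesion-sparse stacks).
    """
    p = probs[:, 1].astype(np.float64)
    t = targets.astype(np.float64)
    num = 2.0 * (p * t).sum() + smooth
    den = p.sum() + t.sum() + smooth
    loss = float(1.0 - num / den)
    dp = -(2.0 * t * den - num) / den**2
    dprobs = np.zeros_like(probs, dtype=np.float64)
    dprobs[:, 1] = dp
    return loss, dprobs


# ---------------------------------------------------------------------------
# training


def _prepare_cohort(cohort, crop_fraction, window=None):
    lo, hi = window if window is not None else (None, None)
    vols, masks = [], []
    for s in cohort:
        if s.mask is None:
            raise ValueError(f"series {s.meta.series_id} has no ground-truth mask")
        if not s.volume.same_geometry(s.mask):
            raise ValueError(f"series {s.meta.series_id}: volume/mask geometry mismatch")
        vols.append(normalize_intensity(s.volume, lo, hi).voxels)
        masks.append(center_crop(s.mask.voxels, crop_fraction) if crop_fraction < 1 else s.mask.voxels)
    return vols, masks


def train(
    model: UNet,
    cohort,
    tcfg: TrainConfig,
    k: int | None = None,
    val_cohort=None,
    transforms=DEFAULT_TRANSFORMS,
    threshold: float = 0.5,
):
    """Train ``model`` on a cohort of annotated series.

    Iterates ``tcfg.epochs`` epochs over every (series, slice) pair: builds
    the k-channel stack, crops, augments with probability ``tcfg.augment_p``
    and takes an Adam step on the batch Dice loss.  The learning rate is
    ``learning_rate * lr_gamma**epoch``.  Returns ``(model, history)`` where
    history is a list of per-epoch dicts (epoch, lr, train_loss, and
    val_dice when a validation cohort is given).  With
    ``tcfg.early_stop_patience`` set, training stops once validation Dice
    has not improved for that many epochs (disabled by default).
    """
    tcfg.validate()
    if not cohort:
        raise ValueError("cohort must be nonempty")
    k = model.config.in_channels if k is None else k
    if k != model.config.in_channels:
        raise ValueError(f"k={k} does not match model in_channels={model.config.in_channels}")

    vols, masks = _prepare_cohort(cohort, tcfg.crop_fraction, tcfg.window)
    rng = np.random.default_rng(tcfg.seed)
    positives = [(si, zi) for si, m in enumerate(masks) for zi in range(m.shape[0]) if m[zi].any()]
    negatives = [(si, zi) for si, m in enumerate(masks) for zi in range(m.shape[0]) if not m[zi].any()]
    if tcfg.empty_slice_fraction is not None and negatives:
        keep = min(len(negatives), int(round(tcfg.empty_slice_fraction * len(positives))))
        idx = rng.choice(len(negatives), size=keep, replace=False)
        negatives = [negatives[i] for i in sorted(idx)]
    samples = positives + negatives
    opt = Adam(model.parameters())

    history: list[dict] = []
    best_val, since_best = -np.inf, 0
    for epoch in range(tcfg.epochs):
        lr = tcfg.learning_rate * tcfg.lr_gamma**epoch
        order = rng.permutation(len(samples))
        losses = []
        for start in range(0, len(order), tcfg.batch_size):
            xs, ts = [], []
            for j in order[start : start + tcfg.batch_size]:
                si, zi = samples[j]
                ch = stack_channels(vols[si], zi, k, tcfg.stack_boundary)
                if tcfg.crop_fraction < 1:
                    ch = center_crop(ch, tcfg.crop_fraction)
                img, msk = augment(
                    ch, masks[si][zi], tcfg.augment_p,
                    seed=int(rng.integers(2**31)), transforms=transforms,
                )
                xs.append(img)
                ts.append(msk)
            x = np.stack(xs).astype(np.float32)
            t = np.stack(ts)
            probs = model.forward(x)
            loss, dprobs = _dice_loss_and_grad(probs, t, tcfg.smooth)
            model.zero_grad()
            model.backward(dprobs)
            opt.step(lr, tcfg.weight_decay)
            losses.append(loss)
        rec = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses))}

        if val_cohort:
            from .evaluation import dice as dice_metric
            from .inference import binarize, predict_volume

            lo, hi = tcfg.window if tcfg.window is not None else (None, None)
            ds = []
            for s in val_cohort:
                vol = normalize_intensity(s.volume, lo, hi)
                prob = predict_volume(
                    model, vol, k=k, use_tta=False,
                    crop_fraction=tcfg.crop_fraction, boundary=tcfg.stack_boundary,
                )
                ds.append(dice_metric(binarize(prob, threshold), s.mask))
            rec["val_dice"] = float(np.mean(ds))
            if rec["val_dice"] > best_val:
                best_val, since_best = rec["val_dice"], 0
            else:
                since_best += 1
        history.append(rec)
        if (
            tcfg.early_stop_patience is not None
            and val_cohort
            and since_best >= tcfg.early_stop_patience
        ):
            break
    return model, history


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: UNet, path: str | Path, seed: int | None = None,
                    extra: dict | None = None) -> None:
    """Save weights + config in one portable .npz file."""
    meta = {"config": asdict(model.config), "seed": seed}
    meta.update(extra or {})
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> tuple[UNet, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        model = UNet(ModelConfig(**meta["config"]))
        params = model.parameters()
        for i, p in enumerate(params):
            p.value[...] = z[f"param_{i}"]
    return model, meta
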