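"""Overlap metrics, stratified cross-validation and mask volumetry.

Metrics: Dice ``2|A∩B| / (|A|+|B|)`` and Jaccard ``|A∩B| / |A∪B|`` with the
empty-empty convention of 1 (a slice without hematoma where none is
predicted is a correct outcome).  By default metrics are computed per
series over the whole 3-D volume; a per-slice aggregation (mean of per-
slice scores) is available as an option.

Cross-validation stratifies on the joint (embolization, hematoma count)
label: within each stratum the series are shuffled by the seed and dealt
round-robin across the folds with a single continuing cursor, so overall
fold sizes differ by at most one and per-fold stratum counts deviate from
exact proportionality by less than one.  Because several series can come
from one patient, folds are grouped by patient by default to avoid leakage
(greedy smallest-fold assignment within each stratum); series-level
stratification is available with ``group_by_patient=False``.

Volumetry: total volume = foreground voxel count x voxel volume (mm^3 ->
mL); per-collection volumes come from 3-D connected components under
26-connectivity, and bilateral collections sum to the total.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import AnnotatedSeries, SeriesMeta
from .inference import binarize, predict_volume
from .unet_core import ModelConfig, TrainConfig, UNet, train
from .volume_io import MaskVolume, normalize_intensity

__all__ = [
    "dice",
    "jaccard",
    "FoldPlan",
    "make_folds",
    "MetricsReport",
    "cross_validate",
    "hematoma_volume",
]


def _as_bool(mask) -> np.ndarray:
    vox = mask.voxels if isinstance(mask, MaskVolume) else np.asarray(mask)
    return vox.astype(bool)


def dice(a, b) -> float:
    """Dice overlap of two binary masks; both empty -> 1 by convention."""
    av, bv = _as_bool(a), _as_bool(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    total = int(av.sum()) + int(bv.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((av & bv).sum()) / total


def jaccard(a, b) -> float:
    """Jaccard index of two binary masks; both empty -> 1 by convention."""
    av, bv = _as_bool(a), _as_bool(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    union = int((av | bv).sum())
    if union == 0:
        return 1.0
    return int((av & bv).sum()) / union


# ---------------------------------------------------------------------------
# folds


@dataclass
class FoldPlan:
    """Assignment of series to stratified cross-validation folds."""

    n_folds: int
    assignment: dict[str, int]  # series_id -> fold index
    strata: dict[str, tuple[bool, int]]  # series_id -> (embolization, hematoma_count)

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.n_folds
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes

    def series_in_fold(self, fold: int) -> list[str]:
        return sorted(sid for sid, f in self.assignment.items() if f == fold)

    def validate(self) -> None:
        folds = set(self.assignment.values())
        if not folds <= set(range(self.n_folds)):
            raise ValueError("fold indices out of range")


def make_folds(
    metas: list[SeriesMeta],
    n_folds: int = 10,
    seed: int = 0,
    group_by_patient: bool = True,
) -> FoldPlan:
    """Build a stratified fold plan over the joint (embolization, count) label.

    The plan is invariant to the input ordering for a given seed (series
    are sorted before shuffling).  With ``group_by_patient`` all series of
    one patient land in the same fold.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(metas):
        raise ValueError(f"n_folds={n_folds} exceeds the number of series ({len(metas)})")
    ids = [m.series_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("series_id values must be unique")

    metas = sorted(metas, key=lambda m: m.series_id)
    strata_of = {m.series_id: (bool(m.embolization), int(m.hematoma_count)) for m in metas}
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}

    if group_by_patient:
        by_patient: dict[str, list[SeriesMeta]] = defaultdict(list)
        for m in metas:
            by_patient[m.patient_id].append(m)
        # a patient's stratum is the lexicographically smallest of its series'
        strata: dict[tuple, list[str]] = defaultdict(list)
        for pid in sorted(by_patient):
            key = min(strata_of[m.series_id] for m in by_patient[pid])
            strata[key].append(pid)
        sizes = [0] * n_folds
        for key in sorted(strata):
            pids = strata[key]
            order = rng.permutation(len(pids))
            # larger patients first, greedily into the currently smallest fold
            pids = sorted(
                (pids[i] for i in order),
                key=lambda p: -len(by_patient[p]),
            )
            for pid in pids:
                fold = int(np.argmin(sizes))
                for m in by_patient[pid]:
                    assignment[m.series_id] = fold
                sizes[fold] += len(by_patient[pid])
    else:
        strata_groups: dict[tuple, list[str]] = defaultdict(list)
        for m in metas:
            strata_groups[strata_of[m.series_id]].append(m.series_id)
        cursor = 0
        for key in sorted(strata_groups):
            sids = strata_groups[key]
            order = rng.permutation(len(sids))
            for i in order:
                assignment[sids[i]] = cursor % n_folds
                cursor += 1

    plan = FoldPlan(n_folds=n_folds, assignment=assignment, strata=strata_of)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# volumetry

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


def hematoma_volume(mask: MaskVolume) -> tuple[float, list[float]]:
    """Total mask volume in mL plus per-component volumes (26-connectivity).

    total = voxel count x row spacing x col spacing x slice spacing / 1000.
    """
    vox_ml = mask.voxel_volume_mm3() / 1000.0
    total = float(mask.voxels.sum()) * vox_ml
    labels, n = ndimage.label(mask.voxels, structure=_CONNECTIVITY_26)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    components = sorted((float(c) * vox_ml for c in counts), reverse=True)
    return total, components


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class MetricsReport:
    """Per-series rows and fold-averaged aggregates of a threshold sweep."""

    rows: pd.DataFrame  # variant, k, threshold, fold, series_id, jaccard, dice, volumes
    n_folds: int

    def validate(self) -> None:
        bad = self.rows[(self.rows.jaccard > self.rows.dice + 1e-12)
                        | (self.rows.dice > 1) | (self.rows.jaccard < 0)]
        if len(bad):
            raise ValueError("metric rows violate 0 <= Jaccard <= Dice <= 1")

    def aggregate(self) -> pd.DataFrame:
        """Unweighted mean over folds (per-fold mean over series first)."""
        per_fold = (
            self.rows.groupby(["variant", "k", "threshold", "fold"], as_index=False)
            [["jaccard", "dice"]].mean()
        )
        return (
            per_fold.groupby(["variant", "k", "threshold"], as_index=False)
            [["jaccard", "dice"]].mean()
        )

    def volumetry(self) -> pd.DataFrame:
        cols = ["series_id", "k", "threshold", "volume_ml_pred", "volume_ml_true"]
        return self.rows[cols].drop_duplicates()

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [f"{self.n_folds}-fold cross-validated overlap (mean over folds)", ""]
        lines.append(f"{'variant':<22}{'threshold':>10}{'Jaccard':>10}{'Dice':>10}")
        for r in agg.itertuples(index=False):
            lines.append(f"{r.variant:<22}{r.threshold:>10.2f}{r.jaccard:>10.4f}{r.dice:>10.4f}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        agg = self.aggregate().assign(fold="mean", series_id="all")
        pd.concat([self.rows, agg], ignore_index=True).to_csv(path, index=False)


def cross_validate(
    cohort: list[AnnotatedSeries],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    k_values=(1, 3, 5),
    thresholds=(0.1, 0.2, 0.3, 0.5, 0.7),
    plan: FoldPlan | None = None,
    use_tta: bool | None = None,
    aggregation: str = "volume",
    model_factory=None,
    verbose: bool = False,
) -> MetricsReport:
    """Stratified cross-validation of the segmentation models.

    For every k in ``k_values`` and every fold: train on the out-of-fold
    series, predict the in-fold series, and score Dice/Jaccard at every
    threshold.  ``aggregation`` is ``"volume"`` (one score per series over
    the whole 3-D mask, the default) or ``"slice"`` (mean of per-slice
    scores).  ``model_factory(train_series, k, fold_seed)`` may replace the
    default build-and-train, e.g. to inject a reference predictor.
    """
    if aggregation not in ("volume", "slice"):
        raise ValueError("aggregation must be 'volume' or 'slice'")
    if plan is None:
        plan = make_folds([s.meta for s in cohort], seed=train_cfg.seed)
    by_id = {s.meta.series_id: s for s in cohort}
    if set(plan.assignment) != set(by_id):
        raise ValueError("fold plan does not cover exactly the cohort's series")

    records = []
    for k in sorted(k_values):
        variant = f"U-Net(2.5D) ({k} slice{'s' if k > 1 else ''})"
        for fold in range(plan.n_folds):
            test_ids = plan.series_in_fold(fold)
            train_series = [by_id[sid] for sid in by_id if sid not in set(test_ids)]
            if not train_series:
                raise ValueError(f"fold {fold} leaves no training series")
            fold_seed = int(np.random.SeedSequence([train_cfg.seed, k, fold]).generate_state(1)[0])
            if model_factory is not None:
                model = model_factory(train_series, k, fold_seed)
            else:
                cfg = replace(model_cfg, in_channels=k)
                model = UNet(cfg, seed=fold_seed % 2**31)
                model, _ = train(model, train_series, replace(train_cfg, seed=fold_seed % 2**31))
            if verbose:
                print(f"[crossval] k={k} fold={fold}: trained on {len(train_series)} series")
            lo, hi = train_cfg.window if train_cfg.window is not None else (None, None)
            for sid in test_ids:
                s = by_id[sid]
                vol = normalize_intensity(s.volume, lo, hi)
                prob = predict_volume(
                    model, vol, k=k, use_tta=use_tta, crop_fraction=train_cfg.crop_fraction
                )
                for thr in sorted(thresholds):
                    pred = binarize(prob, thr)
                    if aggregation == "volume":
                        d = dice(pred, s.mask)
                        j = jaccard(pred, s.mask)
                    else:
                        per = [
                            (dice(pred.voxels[z], s.mask.voxels[z]),
                             jaccard(pred.voxels[z], s.mask.voxels[z]))
                            for z in range(s.mask.n_slices)
                        ]
                        d = float(np.mean([x[0] for x in per]))
                        j = float(np.mean([x[1] for x in per]))
                    records.append(
                        dict(
                            variant=variant,
                            k=k,
                            threshold=thr,
                            fold=fold,
                            series_id=sid,
                            jaccard=j,
                            dice=d,
                            volume_ml_pred=hematoma_volume(pred)[0],
                            volume_ml_true=hematoma_volume(s.mask)[0],
                        )
                    )
    report = MetricsReport(rows=pd.DataFrame.from_records(records), n_folds=plan.n_folds)
    report.validate()
    return report
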