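"""Overlap metrics, stratified folds, cross-validation plumbing, volumetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crescentseg.evaluation import (
    FoldPlan,
    cross_validate,
    dice,
    hematoma_volume,
    jaccard,
    make_folds,
)
from crescentseg.phantom import (
    HUParams,
    SeriesMeta,
    desk_spec,
    generate_cohort,
    paper_default_metas,
)
from crescentseg.unet_core import ModelConfig, TrainConfig
from crescentseg.volume_io import MaskVolume


def _mask(arr):
    return MaskVolume(np.asarray(arr, dtype=np.uint8), (1.0, 1.0), 0.5)


class TestOverlapMetrics:
    def test_identical_and_disjoint(self):
        a = np.zeros((2, 4, 4))
        a[0, :2] = 1
        b = np.zeros((2, 4, 4))
        b[1, 2:] = 1
        assert dice(_mask(a), _mask(a)) == 1.0
        assert jaccard(_mask(a), _mask(a)) == 1.0
        assert dice(_mask(a), _mask(b)) == 0.0
        assert jaccard(_mask(a), _mask(b)) == 0.0

    def test_nested_masks_closed_form(self):
        big = np.zeros((1, 10, 10))
        big.ravel()[:100] = 1
        small = np.zeros_like(big)
        small.ravel()[:50] = 1
        assert dice(_mask(small), _mask(big[: 1])) == pytest.approx(2 * 50 / 150)
        assert jaccard(_mask(small), _mask(big[: 1])) == pytest.approx(0.5)

    def test_empty_empty_convention(self):
        z = _mask(np.zeros((1, 3, 3)))
        assert dice(z, z) == 1.0 and jaccard(z, z) == 1.0

    def test_matches_brute_force_set_arithmetic(self, rng):
        for _ in range(100):
            a = rng.random((4, 16, 16)) < 0.3
            b = rng.random((4, 16, 16)) < 0.3
            sa = {tuple(i) for i in np.argwhere(a)}
            sb = {tuple(i) for i in np.argwhere(b)}
            inter, union = len(sa & sb), len(sa | sb)
            exp_d = 2 * inter / (len(sa) + len(sb)) if (sa or sb) else 1.0
            exp_j = inter / union if union else 1.0
            assert dice(a, b) == exp_d
            assert jaccard(a, b) == exp_j

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_jaccard_dice_identity_and_ordering(self, seed):
        r = np.random.default_rng(seed)
        a = r.random((3, 8, 8)) < 0.4
        b = r.random((3, 8, 8)) < 0.4
        d, j = dice(a, b), jaccard(a, b)
        assert 0 <= j <= d <= 1
        assert j == pytest.approx(d / (2 - d), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            dice(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))


class TestMakeFolds:
    def test_53_series_into_10_series_level_folds(self):
        plan = make_folds(paper_default_metas(), 10, seed=0, group_by_patient=False)
        assert sorted(plan.fold_sizes()) == [5] * 7 + [6] * 3

    def test_stratum_proportionality_within_one(self):
        metas = paper_default_metas()
        plan = make_folds(metas, 10, seed=3, group_by_patient=False)
        for stratum in set(plan.strata.values()):
            sids = [m.series_id for m in metas if plan.strata[m.series_id] == stratum]
            ideal = len(sids) / 10
            for f in range(10):
                got = sum(plan.assignment[sid] == f for sid in sids)
                assert abs(got - ideal) <= 1

    def test_partition_and_seed_reproducibility(self):
        metas = paper_default_metas()
        p1 = make_folds(metas, 10, seed=7)
        p2 = make_folds(metas, 10, seed=7)
        assert p1.assignment == p2.assignment
        assert sorted(p1.assignment) == sorted(m.series_id for m in metas)
        p3 = make_folds(metas, 10, seed=8)
        assert p3.assignment != p1.assignment

    def test_input_order_invariance(self):
        metas = paper_default_metas()
        shuffled = list(reversed(metas))
        a = make_folds(metas, 10, seed=5, group_by_patient=False)
        b = make_folds(shuffled, 10, seed=5, group_by_patient=False)
        assert a.assignment == b.assignment

    def test_single_stratum_degenerates_to_balanced_kfold(self):
        metas = [SeriesMeta(f"s{i}", f"p{i}", False, 1) for i in range(11)]
        plan = make_folds(metas, 4, seed=0, group_by_patient=False)
        assert sorted(plan.fold_sizes()) == [2, 3, 3, 3]

    def test_bilateral_series_dealt_one_or_two_per_fold(self):
        plan = make_folds(paper_default_metas(), 10, seed=1, group_by_patient=False)
        twos = [sid for sid, (_, cnt) in plan.strata.items() if cnt == 2]
        per_fold = [sum(plan.assignment[s] == f for s in twos) for f in range(10)]
        assert set(per_fold) <= {1, 2}  # 13 items round-robin into 10 folds

    def test_patient_grouping_keeps_series_together(self):
        metas = paper_default_metas()
        plan = make_folds(metas, 10, seed=2, group_by_patient=True)
        by_patient = {}
        for m in metas:
            by_patient.setdefault(m.patient_id, set()).add(plan.assignment[m.series_id])
        assert all(len(folds) == 1 for folds in by_patient.values())

    def test_too_many_folds_rejected(self):
        metas = [SeriesMeta("a", "p", False, 1), SeriesMeta("b", "q", False, 1)]
        with pytest.raises(ValueError, match="n_folds"):
            make_folds(metas, 3)


class TestVolumetry:
    def test_voxel_arithmetic(self):
        vox = np.zeros((10, 10, 10), dtype=np.uint8)
        vox.ravel()[:1000] = 1
        total, comps = hematoma_volume(MaskVolume(vox, (1.0, 1.0), 0.5))
        assert total == pytest.approx(0.5)
        assert sum(comps) == pytest.approx(total)

    def test_empty_mask(self):
        total, comps = hematoma_volume(_mask(np.zeros((2, 4, 4))))
        assert total == 0.0 and comps == []

    def test_bilateral_components_sum_to_total(self):
        spec = desk_spec(64, 8, hematoma_count=2, laterality="bilateral")
        from crescentseg.phantom import generate_series

        s = generate_series(spec, seed=4)
        total, comps = hematoma_volume(s.mask)
        assert len(comps) == 2
        assert sum(comps) == pytest.approx(total, abs=1e-9)


class OracleBandModel:
    """Predicts the collection from its intensity plateau (noiseless phantom)."""

    def __init__(self, lo, hi):
        self.lo, self.hi = lo, hi

    def __call__(self, channels):
        mid = channels[channels.shape[0] // 2]
        return ((mid > self.lo) & (mid < self.hi)).astype(np.float64)


@pytest.fixture(scope="module")
def noiseless_cohort():
    spec = desk_spec(
        32, 6, hu_params=HUParams(brain_sd=0, skull_sd=0, collection_sd=0), noise_sd=0.0
    )
    return generate_cohort(4, None, base_spec=spec, seed=13)


class TestCrossValidate:
    def test_oracle_predictor_scores_dice_one_and_counts_runs(self, noiseless_cohort):
        calls = []

        def factory(train_series, k, fold_seed):
            calls.append(len(train_series))
            # normalized plateaus: air 0, brain 40/230, collection 75/230
            return OracleBandModel(60 / 230, 100 / 230)

        plan = make_folds([s.meta for s in noiseless_cohort], 2, seed=0, group_by_patient=False)
        report = cross_validate(
            noiseless_cohort,
            ModelConfig(in_channels=1, depth=2, base_filters=4),
            TrainConfig(epochs=1, crop_fraction=0.875),
            k_values=(1,),
            thresholds=(0.1, 0.3, 0.5, 0.7),
            plan=plan,
            model_factory=factory,
        )
        assert calls == [2, 2]  # two folds, each trained on the other two series
        agg = report.aggregate()
        assert len(agg) == 4  # one aggregate row per threshold
        assert (agg.dice == 1.0).all() and (agg.jaccard == 1.0).all()
        assert (report.rows.jaccard <= report.rows.dice + 1e-12).all()

    def test_report_row_structure_covers_variant_by_threshold(self, noiseless_cohort):
        factory = lambda ts, k, fs: OracleBandModel(60 / 230, 100 / 230)
        plan = make_folds([s.meta for s in noiseless_cohort], 2, seed=0, group_by_patient=False)
        report = cross_validate(
            noiseless_cohort,
            ModelConfig(in_channels=1, depth=2, base_filters=4),
            TrainConfig(epochs=1, crop_fraction=0.875),
            k_values=(1, 3, 5),
            thresholds=(0.1, 0.2, 0.3, 0.5, 0.7),
            plan=plan,
            model_factory=factory,
        )
        agg = report.aggregate()
        assert len(agg) == 15  # 3 variants x 5 thresholds, as in the sweep report
        assert set(agg.k) == {1, 3, 5}
        # per-series volumetry is carried alongside the metrics
        vol = report.volumetry()
        assert set(vol.series_id) == {s.meta.series_id for s in noiseless_cohort}
        assert report.summary().count("U-Net") >= 15

    def test_plan_must_cover_cohort(self, noiseless_cohort):
        plan = make_folds([s.meta for s in noiseless_cohort[:3]], 2, seed=0)
        with pytest.raises(ValueError, match="cover"):
            cross_validate(
                noiseless_cohort,
                ModelConfig(in_channels=1, depth=2, base_filters=4),
                TrainConfig(epochs=1),
                k_values=(1,),
                thresholds=(0.5,),
                plan=plan,
                model_factory=lambda *a: OracleBandModel(0, 1),
            )

    def test_slice_aggregation_also_perfect_for_oracle(self, noiseless_cohort):
        plan = make_folds([s.meta for s in noiseless_cohort], 2, seed=0, group_by_patient=False)
        report = cross_validate(
            noiseless_cohort,
            ModelConfig(in_channels=1, depth=2, base_filters=4),
            TrainConfig(epochs=1, crop_fraction=0.875),
            k_values=(1,),
            thresholds=(0.5,),
            plan=plan,
            aggregation="slice",
            model_factory=lambda *a: OracleBandModel(60 / 230, 100 / 230),
        )
        assert (report.rows.dice == 1.0).all()


def test_fold_plan_validation():
    plan = FoldPlan(2, {"a": 0, "b": 5}, {"a": (False, 1), "b": (False, 1)})
    with pytest.raises(ValueError, match="range"):
        plan.validate()
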