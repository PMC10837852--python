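import numpy as np
import pytest
from scipy import stats

from neurofuse import (
    EffectSpec,
    InvalidArgumentError,
    check_exclusion,
    generate_cohort,
    generate_symmetric_atlas,
    inject_motion_spike,
    mirror_label,
    suggest_target_rois,
)
from neurofuse.pipeline import cohort_feature_tables

SMALL = dict(grid_dims=(10, 10, 8), n_rois=8, n_timepoints=40)


def _roi_cohens_d(table, roi_ids, roi):
    j = list(roi_ids).index(roi)
    a = table.matrix[table.labels == 0, j]
    b = table.matrix[table.labels == 1, j]
    sp = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    return (b.mean() - a.mean()) / sp


class TestSymmetricAtlas:
    def test_labels_cover_mask_and_mirror_pairing(self):
        atlas = generate_symmetric_atlas((8, 8, 8), 4, seed=1)
        assert (atlas.labels > 0).all()
        assert sorted(np.unique(atlas.labels)) == [1, 2, 3, 4]
        mirrored = atlas.labels[::-1]
        paired = np.where(atlas.labels % 2 == 1, atlas.labels + 1, atlas.labels - 1)
        np.testing.assert_array_equal(mirrored, paired)

    def test_116_rois_all_non_empty(self):
        atlas = generate_symmetric_atlas((20, 20, 16), 116, seed=0)
        counts = np.bincount(atlas.labels.ravel(), minlength=117)[1:]
        assert atlas.n_rois == 116
        assert (counts >= 1).all()

    def test_same_seed_identical(self):
        a = generate_symmetric_atlas((8, 8, 8), 6, seed=3)
        b = generate_symmetric_atlas((8, 8, 8), 6, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("grid,n_rois", [((7, 8, 8), 4), ((8, 8, 8), 5)])
    def test_odd_dimensions_rejected(self, grid, n_rois):
        with pytest.raises(InvalidArgumentError):
            generate_symmetric_atlas(grid, n_rois)

    def test_too_many_rois_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_symmetric_atlas((2, 2, 2), 10)

    def test_mirror_label_helper(self):
        assert mirror_label(1) == 2 and mirror_label(2) == 1
        assert mirror_label(7) == 8 and mirror_label(8) == 7


class TestEffectSpec:
    def test_axes_required_for_nonzero_effect(self):
        with pytest.raises(InvalidArgumentError):
            EffectSpec(target_rois={1}, effect_axes=(), effect_size=1.0)

    def test_targets_required_for_nonzero_effect(self):
        with pytest.raises(InvalidArgumentError):
            EffectSpec(effect_axes=("pet_mean",), effect_size=1.0)

    def test_negative_effect_rejected(self):
        with pytest.raises(InvalidArgumentError):
            EffectSpec(target_rois={1}, effect_axes=("pet_mean",), effect_size=-1.0)

    def test_dict_round_trip(self):
        spec = EffectSpec(
            target_rois={1, 3},
            effect_axes=("amplitude", "pet_mean"),
            effect_size={"amplitude": 0.5, "pet_mean": 1.5},
        )
        assert EffectSpec.from_dict(spec.to_dict()) == spec


class TestGenerateCohort:
    def test_empty_bundle_keeps_atlas(self):
        b = generate_cohort(0, 0, **SMALL, seed=1)
        assert b.n_subjects == 0
        assert b.atlas.n_rois == 8

    def test_seed_determinism_is_bitwise(self):
        eff = EffectSpec(target_rois={3}, effect_axes=("pet_mean",), effect_size=1.0)
        a = generate_cohort(2, 2, **SMALL, effect=eff, seed=9)
        b = generate_cohort(2, 2, **SMALL, effect=eff, seed=9)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.bold.data, sb.bold.data)
            np.testing.assert_array_equal(sa.pet.data, sb.pet.data)
            np.testing.assert_array_equal(sa.motion.params, sb.motion.params)

    def test_motion_stays_under_exclusion_limits(self):
        b = generate_cohort(3, 3, **SMALL, seed=2)
        for s in b.subjects:
            assert not check_exclusion(s.motion)

    def test_injected_spike_trips_exclusion(self):
        b = generate_cohort(1, 0, **SMALL, seed=2)
        spiked = inject_motion_spike(b.subjects[0].motion, frame=5)
        assert check_exclusion(spiked)

    def test_unknown_target_roi_rejected(self):
        eff = EffectSpec(target_rois={99}, effect_axes=("pet_mean",), effect_size=1.0)
        with pytest.raises(InvalidArgumentError):
            generate_cohort(1, 1, **SMALL, effect=eff, seed=0)

    def test_pet_effect_detected_by_ttest_at_high_power(self):
        # d = 1.5 at n = 20/20 has power > 0.99 at alpha = 0.01, so every
        # target ROI's SUVR feature must reject
        atlas = generate_symmetric_atlas((10, 10, 8), 8, seed=4)
        targets = suggest_target_rois(atlas, 2, seed=4)
        eff = EffectSpec(
            target_rois=targets, effect_axes=("pet_mean",), effect_size=1.5
        )
        b = generate_cohort(20, 20, **SMALL, effect=eff, seed=4)
        t = cohort_feature_tables(b, modalities=("suvr",))["suvr"]
        ids = list(b.atlas.roi_ids)
        for roi in targets:
            j = ids.index(roi)
            res = stats.ttest_ind(
                t.matrix[t.labels == 1, j], t.matrix[t.labels == 0, j]
            )
            assert res.pvalue < 0.01

    def test_null_cohort_false_positive_rate_near_alpha(self):
        # d = 0: per-ROI two-sample t-tests on SUVR features should reject
        # at about the nominal rate
        alpha = 0.05
        rejections = trials = 0
        for seed in range(30):
            b = generate_cohort(8, 8, **SMALL, seed=seed)
            t = cohort_feature_tables(b, modalities=("suvr",))["suvr"]
            for j in range(t.n_features):
                res = stats.ttest_ind(
                    t.matrix[t.labels == 1, j], t.matrix[t.labels == 0, j]
                )
                rejections += res.pvalue < alpha
                trials += 1
        rate = rejections / trials
        bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / trials)
        assert rate <= bound

    def test_planted_effect_monotone_in_d(self):
        # group separation of the target-ROI SUVR feature grows with d
        mean_d = {}
        for d in (0.0, 0.5, 1.5):
            vals = []
            for seed in range(10):
                if d == 0:
                    eff = EffectSpec()
                else:
                    eff = EffectSpec(
                        target_rois={3}, effect_axes=("pet_mean",), effect_size=d
                    )
                b = generate_cohort(10, 10, **SMALL, effect=eff, seed=seed)
                t = cohort_feature_tables(b, modalities=("suvr",))["suvr"]
                vals.append(_roi_cohens_d(t, b.atlas.roi_ids, 3))
            mean_d[d] = np.mean(vals)
        assert mean_d[0.0] < mean_d[0.5] < mean_d[1.5]


class TestEffectSelectivity:
    def test_each_axis_moves_its_matched_metric_most(self):
        # averaged over seeds, the matched metric's target-ROI effect (in
        # Cohen's d on raw, unstandardised features) dominates the others;
        # dc and fcs are both correlation based, so the hub axis may move
        # either most
        matched = {
            "amplitude": ("falff",),
            "synchrony": ("reho",),
            "hub": ("dc", "fcs"),
            "homotopic": ("vmhc",),
        }
        metrics = ("falff", "reho", "dc", "fcs", "vmhc")
        for axis, expected in matched.items():
            per_metric = {m: [] for m in metrics}
            for seed in range(10):
                eff = EffectSpec(
                    target_rois={3, 5}, effect_axes=(axis,), effect_size=1.5
                )
                b = generate_cohort(
                    10, 10, grid_dims=(10, 10, 8), n_rois=8, n_timepoints=60,
                    effect=eff, seed=seed,
                )
                tables = _raw_tables(b, metrics)
                for m in metrics:
                    per_metric[m].append(
                        np.mean(
                            [
                                abs(_roi_cohens_d(tables[m], b.atlas.roi_ids, r))
                                for r in (3, 5)
                            ]
                        )
                    )
            means = {m: np.mean(v) for m, v in per_metric.items()}
            best = max(means, key=means.get)
            assert best in expected, f"{axis}: {means}"


def _raw_tables(bundle, metrics):
    """Feature tables from raw (unstandardised) metric maps."""
    import numpy as np

    from neurofuse.features import FeatureTable, extract_roi_means
    from neurofuse.pipeline import subject_metric_maps

    rows = {m: [] for m in metrics}
    for s in bundle.subjects:
        maps = subject_metric_maps(
            s.bold, metrics=metrics, voxel_size_mm=bundle.voxel_size_mm,
            standardize=False,
        )
        for m in metrics:
            rows[m].append(extract_roi_means(maps[m], bundle.atlas))
    return {
        m: FeatureTable(np.vstack(v), m, bundle.subject_ids, bundle.labels)
        for m, v in rows.items()
    }


def test_save_cohort_round_trip(tmp_path):
    import nibabel as nib
    import pandas as pd

    from neurofuse import save_cohort

    eff = EffectSpec(target_rois={1}, effect_axes=("pet_mean",), effect_size=1.0)
    b = generate_cohort(1, 1, **SMALL, effect=eff, seed=6)
    save_cohort(b, tmp_path)
    atlas = np.asarray(nib.load(tmp_path / "atlas.nii.gz").dataobj)
    np.testing.assert_array_equal(atlas, b.atlas.labels)
    bold = np.asarray(nib.load(tmp_path / f"{b.subject_ids[0]}_bold.nii.gz").dataobj)
    np.testing.assert_allclose(bold, b.subjects[0].bold.data)
    labels = pd.read_csv(tmp_path / "labels.tsv", sep="\t")
    assert labels["group"].tolist() == [0, 1]
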