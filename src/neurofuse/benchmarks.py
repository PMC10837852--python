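"""Reference simulation studies exercising the whole pipeline.

These are the package's standard end-to-end checks on synthetic cohorts
with known ground truth: classification of a cohort with effects planted
on every axis, recovery of the planted ROIs by the first-layer weight
ranking, calibration under the null, and the benefit of multimodal latent
fusion over the best single modality.  Problem sizes are kept at the
generator's defaults (16x16x12 grid, 20 ROIs, T=170) with 40+40 subjects
for the planted-effect study and 20+20 for the repeated-seed studies.
"""

from __future__ import annotations

from .model import TrainConfig
from .pipeline import cohort_feature_tables, run_experiment
from .features import make_folds
from .synthetic import (
    EFFECT_AXES,
    EffectSpec,
    generate_cohort,
    generate_symmetric_atlas,
    suggest_target_rois,
)

__all__ = [
    "planted_cohort",
    "multimodal_planted_study",
    "suvr_recovery_study",
    "null_auc_study",
    "fusion_study",
]

N_TARGET_ROIS = 5
PLANTED_D = 1.5


def planted_cohort(
    seed: int,
    n_per_group: int = 40,
    axes=EFFECT_AXES,
    effect_size: float | dict = PLANTED_D,
    n_targets: int = N_TARGET_ROIS,
):
    """Default-scale cohort with effects planted in ``n_targets`` ROIs."""
    atlas = generate_symmetric_atlas((16, 16, 12), 20, seed=seed)
    targets = suggest_target_rois(atlas, n_targets, seed=seed)
    effect = EffectSpec(
        target_rois=targets, effect_axes=tuple(axes), effect_size=effect_size
    )
    bundle = generate_cohort(n_per_group, n_per_group, effect=effect, seed=seed)
    return bundle, targets


def multimodal_planted_study(seed: int, n_per_group: int = 40) -> dict:
    """Full six-modality latent-fusion classification of a planted cohort."""
    bundle, targets = planted_cohort(seed, n_per_group=n_per_group)
    tables = cohort_feature_tables(bundle)
    folds = make_folds(bundle.labels, k=5, seed=seed)
    res = run_experiment(
        tables,
        folds,
        TrainConfig(seed=seed),
        mode="multimodal",
        roi_ids=bundle.atlas.roi_ids,
    )
    scores = res.mean_scores()
    return {
        "targets": sorted(targets),
        "accuracy": scores["accuracy"],
        "auc": scores["auc"],
        "scores": scores,
        "sd": res.sd_scores(),
        "result": res,
    }


def suvr_recovery_study(seed: int, n_per_group: int = 40) -> dict:
    """Single-modality PET run; counts planted ROIs in the final top-10."""
    bundle, targets = planted_cohort(seed, n_per_group=n_per_group)
    tables = cohort_feature_tables(bundle, modalities=("suvr",))
    folds = make_folds(bundle.labels, k=5, seed=seed)
    res = run_experiment(
        tables["suvr"],
        folds,
        TrainConfig(seed=seed),
        mode="single",
        roi_ids=bundle.atlas.roi_ids,
    )
    top10 = res.rankings["suvr"].final_rois
    return {
        "targets": sorted(targets),
        "top10": top10,
        "n_recovered": len(set(top10) & set(targets)),
        "accuracy": res.mean_scores()["accuracy"],
        "auc": res.mean_scores()["auc"],
    }


def null_auc_study(seed: int, n_per_group: int = 20) -> float:
    """Mean cross-validated AUC on a no-effect cohort (PET modality)."""
    bundle = generate_cohort(n_per_group, n_per_group, seed=seed)
    tables = cohort_feature_tables(bundle, modalities=("suvr",))
    folds = make_folds(bundle.labels, k=5, seed=seed)
    res = run_experiment(
        tables["suvr"], folds, TrainConfig(seed=seed), mode="single"
    )
    return res.mean_scores()["auc"]


def fusion_study(seed: int, n_per_group: int = 20) -> dict:
    """Complementary effects in two modalities: fALFF vs PET vs fused.

    Half the target ROIs carry only a band-limited amplitude effect (seen
    by fALFF), the other half only a PET mean shift, so neither modality
    alone sees every discriminative ROI.
    """
    atlas = generate_symmetric_atlas((16, 16, 12), 20, seed=seed)
    targets = sorted(suggest_target_rois(atlas, 6, seed=seed))
    amp_targets, pet_targets = targets[:3], targets[3:]
    # each axis is planted in its own half of the targets; two generator
    # passes with axis-specific EffectSpecs keep all other draws seeded
    eff_amp = EffectSpec(
        target_rois=frozenset(amp_targets),
        effect_axes=("amplitude",),
        effect_size=PLANTED_D,
    )
    eff_pet = EffectSpec(
        target_rois=frozenset(pet_targets),
        effect_axes=("pet_mean",),
        effect_size=PLANTED_D,
    )
    bundle_amp = generate_cohort(
        n_per_group, n_per_group, effect=eff_amp, seed=seed
    )
    bundle_pet = generate_cohort(
        n_per_group, n_per_group, effect=eff_pet, seed=seed
    )
    falff = cohort_feature_tables(bundle_amp, modalities=("falff",))["falff"]
    suvr = cohort_feature_tables(bundle_pet, modalities=("suvr",))["suvr"]
    folds = make_folds(bundle_amp.labels, k=5, seed=seed)
    cfg = TrainConfig(seed=seed)
    auc_falff = run_experiment(falff, folds, cfg, mode="single").mean_scores()["auc"]
    auc_suvr = run_experiment(suvr, folds, cfg, mode="single").mean_scores()["auc"]
    auc_multi = run_experiment(
        {"falff": falff, "suvr": suvr}, folds, cfg, mode="multimodal"
    ).mean_scores()["auc"]
    return {
        "amp_targets": amp_targets,
        "pet_targets": pet_targets,
        "auc_falff": auc_falff,
        "auc_suvr": auc_suvr,
        "auc_multimodal": auc_multi,
    }
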