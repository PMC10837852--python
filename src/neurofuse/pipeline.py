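"""End-to-end orchestration: volumes -> metric maps -> ROI features ->
cross-validated AE+MLP classification -> scores and ROI rankings.

Metric-specific processing order:

- fALFF runs on confound-regressed but *unfiltered* data (the ratio must
  see the whole spectrum), spatially smoothed before the spectral step.
- ReHo, DC, FCS and VMHC run on band-passed (0.01-0.08 Hz) data; ReHo and
  DC maps are smoothed *after* standardisation, FCS and VMHC are not
  smoothed.
- fALFF, ReHo, DC and FCS maps are standardised by within-mask z-scoring;
  VMHC (correlation-valued) by the Fisher z-transform.
- PET is normalised to SUVR and then smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError
from .evaluate import (
    RoiRanking,
    ScoreSet,
    aggregate_top_rois,
    classification_scores,
    confusion_counts,
    rank_rois,
    roc_auc,
)
from .features import (
    FeatureTable,
    FoldPlan,
    extract_roi_means,
    make_folds,
    minmax_apply,
    minmax_fit,
)
from .metrics import (
    MetricMap,
    MetricParams,
    compute_dc_fcs,
    compute_falff,
    compute_reho,
    compute_vmhc,
    standardize_map,
)
from .model import (
    TrainConfig,
    encode,
    fuse_latents,
    predict_proba,
    train_autoencoder,
    train_classifier,
)
from .pet import PetVolume, compute_suvr
from .prep import VolumeTimeSeries, bandpass_filter, gaussian_smooth, regress_confounds
from .synthetic import CohortBundle

__all__ = [
    "RSFMRI_METRICS",
    "ALL_MODALITIES",
    "subject_metric_maps",
    "pet_suvr_map",
    "cohort_feature_tables",
    "ExperimentResult",
    "run_experiment",
    "run_cohort_experiment",
]

RSFMRI_METRICS = ("falff", "reho", "dc", "fcs", "vmhc")
ALL_MODALITIES = RSFMRI_METRICS + ("suvr",)


def subject_metric_maps(
    bold: VolumeTimeSeries,
    metrics=RSFMRI_METRICS,
    params: MetricParams = MetricParams(),
    voxel_size_mm: float = 3.0,
    confounds: np.ndarray | None = None,
    standardize: bool = True,
) -> dict[str, MetricMap]:
    """Standardised voxelwise metric maps for one subject."""
    unknown = set(metrics) - set(RSFMRI_METRICS)
    if unknown:
        raise InvalidArgumentError(f"unknown metrics {sorted(unknown)}")
    cleaned = regress_confounds(bold, confounds)
    out: dict[str, MetricMap] = {}

    if "falff" in metrics:
        smoothed = VolumeTimeSeries(
            gaussian_smooth(cleaned.data, params.fwhm_mm, voxel_size_mm, cleaned.mask),
            cleaned.tr_seconds,
            cleaned.mask,
        )
        m = compute_falff(smoothed, params)
        out["falff"] = standardize_map(m, "mask_zscore") if standardize else m

    need_band = set(metrics) & {"reho", "dc", "fcs", "vmhc"}
    if need_band:
        banded = bandpass_filter(cleaned, params.low_hz, params.high_hz)
        if "reho" in metrics:
            m = compute_reho(banded, params)
            if standardize:
                m = standardize_map(m, "mask_zscore")
                m.values = gaussian_smooth(
                    m.values, params.fwhm_mm, voxel_size_mm, m.mask
                )
            out["reho"] = m
        if "dc" in metrics or "fcs" in metrics:
            dc, fcs = compute_dc_fcs(banded, params)
            if "dc" in metrics:
                if standardize:
                    dc = standardize_map(dc, "mask_zscore")
                    dc.values = gaussian_smooth(
                        dc.values, params.fwhm_mm, voxel_size_mm, dc.mask
                    )
                out["dc"] = dc
            if "fcs" in metrics:
                out["fcs"] = standardize_map(fcs, "mask_zscore") if standardize else fcs
        if "vmhc" in metrics:
            m = compute_vmhc(banded)
            out["vmhc"] = standardize_map(m, "fisher_z") if standardize else m
    return out


def pet_suvr_map(
    pet: PetVolume,
    fwhm_mm: float = 6.0,
    voxel_size_mm: float = 3.0,
) -> MetricMap:
    """SUVR map, smoothed after normalisation."""
    m = compute_suvr(pet)
    if fwhm_mm > 0:
        m.values = gaussian_smooth(m.values, fwhm_mm, voxel_size_mm, m.mask)
    return m


def cohort_feature_tables(
    bundle: CohortBundle,
    modalities=ALL_MODALITIES,
    params: MetricParams = MetricParams(),
    regress_motion: bool = True,
) -> dict[str, FeatureTable]:
    """Per-modality subjects x ROIs feature tables for a whole cohort."""
    modalities = tuple(modalities)
    unknown = set(modalities) - set(ALL_MODALITIES)
    if unknown:
        raise InvalidArgumentError(f"unknown modalities {sorted(unknown)}")
    fmri = tuple(m for m in modalities if m in RSFMRI_METRICS)
    rows: dict[str, list[np.ndarray]] = {m: [] for m in modalities}
    for s in bundle.subjects:
        if fmri:
            confounds = s.motion.params if regress_motion else None
            maps = subject_metric_maps(
                s.bold,
                metrics=fmri,
                params=params,
                voxel_size_mm=bundle.voxel_size_mm,
                confounds=confounds,
            )
            for name in fmri:
                rows[name].append(extract_roi_means(maps[name], bundle.atlas))
        if "suvr" in modalities:
            suvr = pet_suvr_map(
                s.pet, fwhm_mm=params.fwhm_mm, voxel_size_mm=bundle.voxel_size_mm
            )
            rows["suvr"].append(extract_roi_means(suvr, bundle.atlas))
    return {
        name: FeatureTable(
            np.vstack(vals) if vals else np.empty((0, bundle.atlas.n_rois)),
            name,
            bundle.subject_ids,
            bundle.labels,
        )
        for name, vals in rows.items()
    }


@dataclass
class ExperimentResult:
    """Cross-validated scores, per-fold predictions and ROI rankings."""

    mode: str
    modalities: tuple[str, ...]
    fold_scores: list[ScoreSet]
    fold_predictions: list[tuple[np.ndarray, np.ndarray]]  # (y_true, y_prob)
    rankings: dict[str, RoiRanking]
    per_fold_rankings: dict[str, list] = field(default_factory=dict, repr=False)

    def mean_scores(self) -> dict[str, float]:
        out = {}
        for key in ScoreSet().as_dict():
            vals = [s.as_dict()[key] for s in self.fold_scores]
            vals = [v for v in vals if v is not None]
            if vals:
                out[key] = float(np.mean(vals))
        return out

    def sd_scores(self) -> dict[str, float]:
        out = {}
        for key in ScoreSet().as_dict():
            vals = [s.as_dict()[key] for s in self.fold_scores]
            vals = [v for v in vals if v is not None]
            if vals:
                out[key] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return out


def _fold_seed(base_seed: int, fold: int, salt: int) -> int:
    state = np.random.SeedSequence([base_seed, fold, salt]).generate_state(1)[0]
    return int(state % (2**31))


def _fold_scoreset(y_true, y_prob) -> ScoreSet:
    scores = classification_scores(confusion_counts(y_true, y_prob))
    _, auc = roc_auc(y_true, y_prob)
    scores.auc = auc
    return scores


def run_experiment(
    tables: dict[str, FeatureTable] | FeatureTable,
    folds: FoldPlan,
    cfg: TrainConfig = TrainConfig(),
    mode: str = "single",
    d_latent: int | None = None,
    roi_ids=None,
    top_k: int = 10,
) -> ExperimentResult:
    """Cross-validated AE-pretrained MLP classification.

    ``single`` mode takes one feature table; per fold, an autoencoder is
    trained on the scaled training rows and its encoder becomes the
    classifier's first layer, fine-tuned end-to-end.  ``multimodal`` mode
    takes several tables; per fold, one frozen autoencoder per modality
    embeds the features and the concatenated latents feed a fresh MLP.
    ROI rankings come from the first-layer weights (fine-tuned in single
    mode, the unsupervised encoders in multimodal mode), aggregated across
    folds by top-k selection frequency.
    """
    if isinstance(tables, FeatureTable):
        tables = {tables.modality: tables}
    if mode not in ("single", "multimodal"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    if mode == "single" and len(tables) != 1:
        raise InvalidArgumentError("single mode takes exactly one feature table")
    if not tables:
        raise InvalidArgumentError("no feature tables given")

    names = tuple(tables)
    first = tables[names[0]]
    for t in tables.values():
        if t.subject_ids != first.subject_ids or not np.array_equal(
            t.labels, first.labels
        ):
            raise InvalidArgumentError("tables must share subject order and labels")
    labels = first.labels

    fold_scores: list[ScoreSet] = []
    fold_predictions = []
    per_fold_rankings: dict[str, list] = {name: [] for name in names}

    for fold_i, (tr_idx, te_idx) in enumerate(folds.folds):
        y_tr, y_te = labels[tr_idx], labels[te_idx]
        latents_tr, latents_te = [], []
        for mod_i, name in enumerate(names):
            table = tables[name]
            d = d_latent or min(cfg.hidden_sizes[0], table.n_features - 1)
            scaler = minmax_fit(table.rows(tr_idx))
            train_s = minmax_apply(table.rows(tr_idx), scaler)
            test_s = minmax_apply(table.rows(te_idx), scaler)
            ae_cfg = replace(cfg, seed=_fold_seed(cfg.seed, fold_i, 2 * mod_i))
            ae = train_autoencoder(train_s, d, ae_cfg)
            if mode == "single":
                clf_cfg = replace(cfg, seed=_fold_seed(cfg.seed, fold_i, 2 * mod_i + 1))
                clf = train_classifier(
                    train_s.matrix, y_tr, clf_cfg, encoder_init=ae
                )
                y_prob = predict_proba(clf, test_s.matrix)
                per_fold_rankings[name].append(rank_rois(clf.weights[0], roi_ids))
            else:
                latents_tr.append(encode(ae, train_s))
                latents_te.append(encode(ae, test_s))
                per_fold_rankings[name].append(rank_rois(ae, roi_ids))
        if mode == "multimodal":
            x_tr = fuse_latents(latents_tr)
            x_te = fuse_latents(latents_te)
            clf_cfg = replace(cfg, seed=_fold_seed(cfg.seed, fold_i, 9999))
            clf = train_classifier(x_tr, y_tr, clf_cfg)
            y_prob = predict_proba(clf, x_te)

        fold_scores.append(_fold_scoreset(y_te, y_prob))
        fold_predictions.append((y_te, y_prob))

    rankings = {
        name: aggregate_top_rois(per_fold_rankings[name], k=top_k) for name in names
    }
    return ExperimentResult(
        mode=mode,
        modalities=names,
        fold_scores=fold_scores,
        fold_predictions=fold_predictions,
        rankings=rankings,
        per_fold_rankings=per_fold_rankings,
    )


def run_cohort_experiment(
    bundle: CohortBundle,
    modalities=("suvr",),
    mode: str = "single",
    cfg: TrainConfig = TrainConfig(),
    k: int = 5,
    params: MetricParams = MetricParams(),
) -> ExperimentResult:
    """Convenience wrapper: cohort -> feature tables -> folds -> experiment."""
    tables = cohort_feature_tables(bundle, modalities=modalities, params=params)
    folds = make_folds(bundle.labels, k=k, seed=cfg.seed)
    return run_experiment(
        tables if mode == "multimodal" else tables[modalities[0]],
        folds,
        cfg,
        mode=mode,
        roi_ids=bundle.atlas.roi_ids,
    )
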