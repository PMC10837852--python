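"""ROI feature extraction, scaling and cross-validation folds.

Reduces voxelwise metric maps to per-subject ROI-mean feature vectors using
an integer-labelled atlas, assembles per-modality subjects-by-ROI feature
tables, min-max scales features on training rows only, and builds
stratified k-fold plans (each fold serving once as the held-out 20% in the
5-fold default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import InvalidArgumentError, MissingRoiError
from .metrics import MetricMap

__all__ = [
    "Atlas",
    "FeatureTable",
    "ScalerParams",
    "FoldPlan",
    "extract_roi_means",
    "minmax_fit",
    "minmax_apply",
    "make_folds",
]


@dataclass
class Atlas:
    """An integer-labelled parcellation grid (0 = background)."""

    labels: np.ndarray
    roi_ids: np.ndarray = None
    roi_names: list[str] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InvalidArgumentError("atlas labels must be integers")
        present = np.unique(self.labels)
        present = present[present > 0]
        if self.roi_ids is None:
            self.roi_ids = present
        else:
            self.roi_ids = np.asarray(self.roi_ids, dtype=int)
            if (np.diff(self.roi_ids) <= 0).any():
                raise InvalidArgumentError("roi_ids must be sorted, unique")
            if not np.isin(self.roi_ids, present).all():
                missing = set(self.roi_ids) - set(present)
                raise InvalidArgumentError(
                    f"roi_ids absent from the label grid: {sorted(missing)}"
                )
        if self.roi_names is not None and len(self.roi_names) != len(self.roi_ids):
            raise InvalidArgumentError("roi_names length must match roi_ids")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def name_of(self, roi_id: int) -> str:
        if self.roi_names is None:
            return f"roi_{roi_id}"
        return self.roi_names[int(np.searchsorted(self.roi_ids, roi_id))]


@dataclass
class FeatureTable:
    """Subjects x ROIs feature matrix for one modality with binary labels.

    Label convention: 0 = control (negative class), 1 = case (positive).
    """

    matrix: np.ndarray
    modality: str
    subject_ids: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise InvalidArgumentError("feature matrix must be 2D")
        if len(self.subject_ids) != self.matrix.shape[0]:
            raise InvalidArgumentError("subject_ids length must match rows")
        if len(self.labels) != self.matrix.shape[0]:
            raise InvalidArgumentError("labels length must match rows")
        if not np.isin(self.labels, [0, 1]).all():
            raise InvalidArgumentError("labels must be binary 0/1")
        if self.matrix.size and not np.isfinite(self.matrix).all():
            raise InvalidArgumentError("non-finite feature values")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def rows(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            self.matrix[idx],
            self.modality,
            [self.subject_ids[i] for i in idx],
            self.labels[idx],
        )

    def to_frame(self, roi_ids=None) -> pd.DataFrame:
        cols = (
            [f"roi_{r}" for r in roi_ids]
            if roi_ids is not None
            else [f"f{j}" for j in range(self.n_features)]
        )
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        return df

    def to_tsv(self, path, roi_ids=None) -> None:
        self.to_frame(roi_ids).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, modality: str) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        feature_cols = [c for c in df.columns if c not in ("subject_id", "label")]
        return cls(
            df[feature_cols].to_numpy(float),
            modality,
            df["subject_id"].astype(str).tolist(),
            df["label"].to_numpy(int),
        )


@dataclass
class ScalerParams:
    """Per-feature min/max learned from training rows only."""

    min_: np.ndarray
    max_: np.ndarray
    degenerate: np.ndarray  # constant training columns (mapped to 0)

    def __post_init__(self):
        if (self.max_ < self.min_).any():
            raise InvalidArgumentError("max must be >= min elementwise")


def extract_roi_means(m: MetricMap, atlas: Atlas) -> np.ndarray:
    """Mean metric value per atlas ROI.

    Only in-mask, non-missing voxels contribute.  An ROI with no usable
    voxel raises :class:`MissingRoiError` listing the offending ids.
    """
    if m.values.shape != atlas.labels.shape:
        raise InvalidArgumentError("metric map and atlas grids differ")
    valid = m.valid
    out = np.empty(atlas.n_rois)
    empty = []
    for i, roi in enumerate(atlas.roi_ids):
        sel = (atlas.labels == roi) & valid
        if not sel.any():
            empty.append(int(roi))
            continue
        out[i] = m.values[sel].mean()
    if empty:
        raise MissingRoiError(empty)
    return out


def minmax_fit(train: FeatureTable) -> ScalerParams:
    """Learn per-feature min/max from training rows (0-1 scaling)."""
    if train.n_subjects == 0:
        raise InvalidArgumentError("cannot fit scaler on an empty table")
    lo = train.matrix.min(axis=0)
    hi = train.matrix.max(axis=0)
    return ScalerParams(lo, hi, degenerate=hi <= lo)


def minmax_apply(t: FeatureTable, s: ScalerParams) -> FeatureTable:
    """Apply min-max scaling; training rows land in [0, 1] exactly.

    Test rows may exceed [0, 1] (no clipping).  Features constant in the
    training data map to 0.
    """
    if t.n_features != len(s.min_):
        raise InvalidArgumentError("scaler width does not match table")
    span = np.where(s.degenerate, 1.0, s.max_ - s.min_)
    scaled = (t.matrix - s.min_) / span
    scaled[:, s.degenerate] = 0.0
    return FeatureTable(scaled, t.modality, list(t.subject_ids), t.labels.copy())


@dataclass
class FoldPlan:
    """K disjoint test folds covering every subject exactly once."""

    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    k: int
    seed: int
    stratified: bool = True

    def __post_init__(self):
        n = sum(len(te) for _, te in self.folds)
        covered = np.sort(np.concatenate([te for _, te in self.folds]))
        if not np.array_equal(covered, np.arange(n)):
            raise InvalidArgumentError("test folds must partition all subjects")


def make_folds(
    labels, k: int = 5, seed: int = 0, stratified: bool = True
) -> FoldPlan:
    """Build a shuffled (optionally stratified) k-fold cross-validation plan.

    Each fold serves once as the held-out test split; with k=5 this is the
    80:20 train/test scheme repeated five times.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise InvalidArgumentError("k must be at least 2")
    if len(labels) < k:
        raise InvalidArgumentError("fewer subjects than folds")
    if stratified:
        counts = np.bincount(labels, minlength=2)
        if (counts[counts > 0] < k).any():
            raise InvalidArgumentError(
                f"each class needs >= k={k} members for stratified folds"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(labels)), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(labels)))
    folds = [(np.asarray(tr), np.asarray(te)) for tr, te in split]
    return FoldPlan(folds, k=k, seed=seed, stratified=stratified)
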