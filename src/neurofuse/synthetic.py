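"""Synthetic two-group cohort generator with planted, localised effects.

Every downstream stage (temporal preprocessing, voxelwise metrics, SUVR,
ROI features, classification, ROI ranking) is testable without external
data: the generator emits BOLD-like 4D volumes, motion traces and PET
volumes for a control group and a case group, together with a
mirror-symmetric atlas and a ground-truth record of which ROIs carry a
group difference along which axis.

Each effect axis perturbs only its matched metric's sensitive feature in
the target ROIs of case subjects:

- ``amplitude``: independent per-voxel band-limited (0.01-0.08 Hz) signals
  raise in-band spectral amplitude (fALFF) without adding synchrony.
- ``synchrony``: a common broadband signal shared by all voxels of an ROI
  raises local rank concordance (ReHo); being broadband it leaves the
  in-band/total amplitude ratio (fALFF) unchanged.
- ``hub``: a broadband signal shared, with random per-voxel signs, between
  all voxels of a target ROI and a diffuse subset of voxels spread across
  every other ROI pushes long-range correlations past the DC/FCS
  thresholds.  The target is fully involved while other ROIs are involved
  only fractionally, so the planted hub stands out; the random signs keep
  local concordance (ReHo) low.
- ``homotopic``: per mirrored-voxel-pair broadband signals (independent
  across pairs) raise interhemispheric correlation (VMHC) only.
- ``pet_mean``: a mean shift of d * noise_sd in the target ROIs of the PET
  volume, where noise_sd is the between-subject SD of ROI-level uptake, so
  the requested d is the feature-level Cohen's d.

The BOLD effect amplitudes are scaled by per-axis gain constants calibrated
once (simulation on the default grid) so that a requested d of 1 produces
a target-ROI feature separation of roughly one within-group SD; they are
approximate for the BOLD axes and exact by construction for ``pet_mean``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .features import Atlas
from .io import (
    save_labels_tsv,
    save_motion_tsv,
    save_nifti,
    save_nifti_int,
)
from .pet import PetVolume
from .prep import MotionTrace, VolumeTimeSeries

__all__ = [
    "EFFECT_AXES",
    "EffectSpec",
    "SubjectRecord",
    "CohortBundle",
    "generate_symmetric_atlas",
    "generate_cohort",
    "mirror_label",
    "suggest_target_rois",
    "inject_motion_spike",
    "save_cohort",
]

EFFECT_AXES = ("amplitude", "synchrony", "hub", "homotopic", "pet_mean")

# Per-axis amplitude gains: BOLD effect amplitude = d * gain (in units of
# the voxel noise SD).  Calibrated on the default 16x16x12 / 20-ROI grid so
# the target-ROI feature shift is about d within-group SDs.
AXIS_GAIN = {
    "amplitude": 0.45,
    "synchrony": 0.42,
    "hub": 0.90,
    "homotopic": 0.28,
}

#: Baseline PET uptake in arbitrary counts; cancels in SUVR.
PET_BASELINE = 10.0
#: Fraction of non-target voxels wired to each hub-axis target ROI.
HUB_DIFFUSE_FRACTION = 0.08
#: SD of per-voxel loadings on the shared low-frequency background.
BACKGROUND_LOADING_SD = 0.15


@dataclass(frozen=True)
class EffectSpec:
    """Ground truth of the planted group difference.

    ``effect_size`` is either one Cohen's d applied to every requested axis
    or a mapping axis -> d.  ``noise_sd`` sets the between-subject SD of
    ROI-level PET uptake (arbitrary intensity units).
    """

    target_rois: frozenset[int] = frozenset()
    effect_axes: tuple[str, ...] = ()
    effect_size: float | dict = 0.0
    noise_sd: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "target_rois", frozenset(int(r) for r in self.target_rois))
        object.__setattr__(self, "effect_axes", tuple(self.effect_axes))
        unknown = set(self.effect_axes) - set(EFFECT_AXES)
        if unknown:
            raise InvalidArgumentError(f"unknown effect axes {sorted(unknown)}")
        if self.noise_sd <= 0:
            raise InvalidArgumentError("noise_sd must be positive")
        raw = (
            list(self.effect_size.values())
            if isinstance(self.effect_size, dict)
            else [self.effect_size]
        )
        if any(d < 0 for d in raw):
            raise InvalidArgumentError("effect sizes must be non-negative")
        if any(d > 0 for d in raw):
            if not self.effect_axes:
                raise InvalidArgumentError(
                    "nonzero effect_size requires at least one effect axis"
                )
            if not self.target_rois:
                raise InvalidArgumentError(
                    "nonzero effect_size requires non-empty target_rois"
                )

    def axis_sizes(self) -> dict[str, float]:
        """Resolved Cohen's d per requested axis."""
        if isinstance(self.effect_size, dict):
            return {a: float(self.effect_size.get(a, 0.0)) for a in self.effect_axes}
        return {a: float(self.effect_size) for a in self.effect_axes}

    def to_dict(self) -> dict:
        return {
            "target_rois": sorted(self.target_rois),
            "effect_axes": list(self.effect_axes),
            "effect_size": (
                dict(self.effect_size)
                if isinstance(self.effect_size, dict)
                else self.effect_size
            ),
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        return cls(
            target_rois=frozenset(d.get("target_rois", ())),
            effect_axes=tuple(d.get("effect_axes", ())),
            effect_size=d.get("effect_size", 0.0),
            noise_sd=d.get("noise_sd", 0.5),
        )


@dataclass
class SubjectRecord:
    subject_id: str
    bold: VolumeTimeSeries
    motion: MotionTrace
    pet: PetVolume


@dataclass
class CohortBundle:
    """A generated cohort plus its atlas and ground truth."""

    subjects: list[SubjectRecord]
    labels: np.ndarray  # 0 = control, 1 = case
    atlas: Atlas
    truth: EffectSpec
    seed: int
    voxel_size_mm: float = 3.0
    tr_seconds: float = 2.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.subjects):
            raise InvalidArgumentError("labels length must equal subject count")
        grid = self.atlas.labels.shape
        for s in self.subjects:
            if s.bold.grid_shape != grid or s.pet.data.shape != grid:
                raise InvalidArgumentError("subject grids must match the atlas")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def mirror_label(label: int) -> int:
    """The contralateral partner of a label: pairs are (2k-1, 2k)."""
    return label + 1 if label % 2 == 1 else label - 1


def generate_symmetric_atlas(grid_dims, n_rois: int, seed: int = 0) -> Atlas:
    """Random Voronoi parcellation, mirror-symmetric across the x mid-plane.

    ``n_rois // 2`` seed voxels are drawn in the left half (x < X/2); each
    left voxel joins its nearest seed (label 2k-1) and the right half is
    the exact mirror (label 2k), so the plane between columns X/2 - 1 and
    X/2 maps label 1 <-> 2, 3 <-> 4, ...  Every label is non-empty (each
    seed labels at least its own voxel).
    """
    x, y, z = (int(v) for v in grid_dims)
    if x % 2 != 0:
        raise InvalidArgumentError("grid x-dimension must be even")
    if n_rois % 2 != 0 or n_rois < 2:
        raise InvalidArgumentError("n_rois must be even and >= 2")
    half_voxels = (x // 2) * y * z
    if n_rois // 2 > half_voxels:
        raise InvalidArgumentError("n_rois exceeds the voxel count")

    rng = np.random.default_rng(seed)
    half = x // 2
    coords = np.stack(
        np.meshgrid(np.arange(half), np.arange(y), np.arange(z), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    seed_idx = rng.choice(len(coords), size=n_rois // 2, replace=False)
    seeds = coords[seed_idx]

    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)  # ties -> lowest seed index
    left = (2 * nearest + 1).reshape(half, y, z)

    labels = np.empty((x, y, z), dtype=np.int32)
    labels[:half] = left
    labels[half:] = (left + 1)[::-1]
    names = []
    for k in range(n_rois // 2):
        names += [f"roi_{2 * k + 1:03d}_L", f"roi_{2 * k + 2:03d}_R"]
    ids = np.arange(1, n_rois + 1)
    # interleave names to match sorted ids
    names = [f"roi_{i:03d}_{'L' if i % 2 else 'R'}" for i in ids]
    return Atlas(labels, roi_ids=ids, roi_names=names)


def _reference_mask(grid_dims) -> np.ndarray:
    """Inferior-slab PET reference region (cerebellar stand-in): z = 0."""
    mask = np.zeros(grid_dims, dtype=bool)
    mask[:, :, 0] = True
    return mask


def suggest_target_rois(
    atlas: Atlas, n: int, seed: int = 0, avoid_reference: bool = True
) -> frozenset[int]:
    """Pick ``n`` candidate target ROIs, avoiding the PET reference slab.

    ROIs with more than half their voxels inside the reference slab are
    skipped so a planted PET shift is not absorbed by the normaliser.
    """
    rng = np.random.default_rng(seed)
    ref = _reference_mask(atlas.labels.shape)
    eligible = []
    for roi in atlas.roi_ids:
        sel = atlas.labels == roi
        if avoid_reference and (sel & ref).sum() > 0.5 * sel.sum():
            continue
        eligible.append(int(roi))
    if n > len(eligible):
        raise InvalidArgumentError(f"only {len(eligible)} eligible ROIs for n={n}")
    chosen = rng.choice(len(eligible), size=n, replace=False)
    return frozenset(eligible[i] for i in chosen)


def _band_limited_rows(rng, n_rows, n_t, tr, low=0.01, high=0.08):
    """Unit-SD rows of band-limited Gaussian noise (FFT masking)."""
    white = rng.standard_normal((n_rows, n_t))
    spect = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_t, d=tr)
    spect[:, ~((freqs >= low) & (freqs <= high))] = 0.0
    sig = np.fft.irfft(spect, n=n_t, axis=1)
    sd = sig.std(axis=1, keepdims=True)
    sd[sd <= 0] = 1.0
    return sig / sd


def _motion_trace(rng, n_t) -> MotionTrace:
    """Small random-walk motion bounded inside the exclusion limits."""
    steps = np.column_stack(
        [
            rng.normal(0.0, 0.02, size=(n_t, 3)),  # translations, mm
            rng.normal(0.0, 3e-4, size=(n_t, 3)),  # rotations, rad
        ]
    )
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    # rescale so |translation| < 0.5 mm and |rotation| < 0.5 deg always hold
    t_max = np.abs(params[:, :3]).max()
    r_max = np.abs(params[:, 3:]).max()
    if t_max > 0.4:
        params[:, :3] *= 0.4 / t_max
    rot_bound = np.radians(0.4)
    if r_max > rot_bound:
        params[:, 3:] *= rot_bound / r_max
    return MotionTrace(params)


def inject_motion_spike(
    m: MotionTrace, frame: int, translation_mm: float = 2.5, axis: int = 0
) -> MotionTrace:
    """Return a copy of the trace with one frame pushed past the 2 mm rule."""
    params = m.params.copy()
    if not 0 <= frame < params.shape[0]:
        raise InvalidArgumentError("spike frame out of range")
    params[frame, axis] += translation_mm
    return MotionTrace(params)


def _hub_wiring(rng, atlas: Atlas, targets) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Fixed hub wiring per target ROI (shared across all subjects).

    Each target ROI shares a subject-specific broadband signal with all of
    its own voxels plus a random ``HUB_DIFFUSE_FRACTION`` of the remaining
    voxels, every participant carrying a random +-1 loading.  Returns, per
    target, the flat voxel indices involved and their signs.
    """
    flat_labels = atlas.labels.ravel()
    wiring = {}
    for roi in sorted(targets):
        own = np.flatnonzero(flat_labels == roi)
        others = np.flatnonzero(flat_labels != roi)
        n_diffuse = int(round(HUB_DIFFUSE_FRACTION * len(others)))
        diffuse = rng.choice(others, size=n_diffuse, replace=False)
        idx = np.concatenate([own, diffuse])
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        wiring[roi] = (idx, signs)
    return wiring


def _mirror_pairs(coords, x_dim):
    """Deduplicated (voxel, mirror) index pairs from an ROI coordinate list."""
    seen = set()
    pairs = []
    for c in coords:
        m = (x_dim - 1 - c[0], c[1], c[2])
        key = (min(tuple(c), m), max(tuple(c), m))
        if key in seen or tuple(c) == m:
            continue
        seen.add(key)
        pairs.append((tuple(c), m))
    return pairs


def _generate_bold(
    rng,
    grid,
    n_t,
    tr,
    is_case,
    atlas,
    axis_d,
    hub_wiring,
):
    """One subject's 4D BOLD-like volume with any planted case effects."""
    x, y, z = grid
    data = rng.standard_normal((x, y, z, n_t))

    # Shared low-frequency background: 3 in-band sinusoids whose loadings
    # are drawn per ROI (plus per-voxel jitter).  This prevents degenerate
    # all-noise spectra and gives every metric a realistic baseline: local
    # concordance within ROIs, a moderate spread of long-range
    # correlations, and subject-to-subject feature variability.
    t_axis = np.arange(n_t) * tr
    roi_index = atlas.labels
    for _ in range(3):
        freq = rng.uniform(0.01, 0.08)
        phase = rng.uniform(0, 2 * np.pi)
        s = np.sqrt(2.0) * np.sin(2 * np.pi * freq * t_axis + phase)
        roi_loading = rng.normal(0.0, BACKGROUND_LOADING_SD, size=roi_index.max() + 1)
        loadings = roi_loading[roi_index] + rng.normal(
            0.0, BACKGROUND_LOADING_SD / 2, size=(x, y, z)
        )
        data += loadings[..., None] * s

    if not is_case:
        return data

    if axis_d.get("amplitude", 0.0) > 0:
        amp = axis_d["amplitude"] * AXIS_GAIN["amplitude"]
        for roi in sorted(axis_d["_targets"]):
            sel = atlas.labels == roi
            n_vox = int(sel.sum())
            data[sel] += amp * _band_limited_rows(rng, n_vox, n_t, tr)

    if axis_d.get("synchrony", 0.0) > 0:
        amp = axis_d["synchrony"] * AXIS_GAIN["synchrony"]
        for roi in sorted(axis_d["_targets"]):
            sel = atlas.labels == roi
            common = rng.standard_normal(n_t)
            data[sel] += amp * common

    if axis_d.get("hub", 0.0) > 0:
        amp = axis_d["hub"] * AXIS_GAIN["hub"]
        flat = data.reshape(-1, n_t)
        for roi in sorted(axis_d["_targets"]):
            common = rng.standard_normal(n_t)
            idx, signs = hub_wiring[roi]
            flat[idx] += amp * signs[:, None] * common

    if axis_d.get("homotopic", 0.0) > 0:
        amp = axis_d["homotopic"] * AXIS_GAIN["homotopic"]
        for roi in sorted(axis_d["_targets"]):
            coords = np.argwhere(atlas.labels == roi)
            pairs = _mirror_pairs(coords, x)
            if not pairs:
                continue
            sigs = rng.standard_normal((len(pairs), n_t))
            for (a, b), s in zip(pairs, sigs):
                data[a] += amp * s
                data[b] += amp * s

    return data


def _generate_pet(rng, grid, atlas, ref_mask, is_case, d_pet, targets, noise_sd):
    """One subject's PET volume: baseline + ROI-level noise (+ case shift).

    The reference slab is excluded from ROI-level noise and shift (the
    reference region is chosen for stable uptake), so SUVR features carry
    a between-subject SD of ~noise_sd / baseline and a case shift of
    d * noise_sd / baseline: the requested d is the feature-level Cohen's d.
    """
    data = np.full(grid, PET_BASELINE)
    outside_ref = ~ref_mask
    for roi in atlas.roi_ids:
        sel = (atlas.labels == roi) & outside_ref
        offset = rng.normal(0.0, noise_sd)
        if is_case and d_pet > 0 and int(roi) in targets:
            offset += d_pet * noise_sd
        data[sel] += offset
    data += rng.normal(0.0, noise_sd, size=grid)
    data *= rng.uniform(0.9, 1.1)  # global dose/gain factor; SUVR removes it
    np.clip(data, 0.0, None, out=data)
    mask = np.ones(grid, dtype=bool)
    return PetVolume(data, mask, ref_mask)


def generate_cohort(
    n_control: int,
    n_case: int,
    grid_dims=(16, 16, 12),
    n_rois: int = 20,
    tr_seconds: float = 2.0,
    n_timepoints: int = 170,
    effect: EffectSpec = EffectSpec(),
    seed: int = 0,
    voxel_size_mm: float = 3.0,
) -> CohortBundle:
    """Generate a deterministic two-group cohort with planted effects.

    Controls precede cases in subject order; the atlas, hub wiring and all
    subject data derive from ``seed`` alone, so identical arguments give
    bit-identical bundles.
    """
    if n_control < 0 or n_case < 0:
        raise InvalidArgumentError("group sizes must be non-negative")
    if n_timepoints < 20:
        raise InvalidArgumentError("need at least 20 time points")
    if tr_seconds <= 0:
        raise InvalidArgumentError("tr_seconds must be positive")

    atlas = generate_symmetric_atlas(grid_dims, n_rois, seed=seed)
    grid = atlas.labels.shape
    axis_d = effect.axis_sizes()
    targets = set(effect.target_rois)
    unknown_targets = targets - {int(r) for r in atlas.roi_ids}
    if unknown_targets:
        raise InvalidArgumentError(
            f"target ROIs absent from atlas: {sorted(unknown_targets)}"
        )
    axis_d["_targets"] = targets

    ss = np.random.SeedSequence(seed)
    wiring_rng = np.random.default_rng(ss.spawn(1)[0])
    hub_wiring = {}
    if axis_d.get("hub", 0.0) > 0:
        hub_wiring = _hub_wiring(wiring_rng, atlas, targets)

    ref_mask = _reference_mask(grid)
    n_total = n_control + n_case
    subject_seeds = ss.spawn(n_total + 1)[1:]
    labels = np.array([0] * n_control + [1] * n_case, dtype=int)
    mask = np.ones(grid, dtype=bool)

    subjects = []
    for i in range(n_total):
        rng = np.random.default_rng(subject_seeds[i])
        is_case = labels[i] == 1
        bold = _generate_bold(
            rng,
            grid,
            n_timepoints,
            tr_seconds,
            is_case,
            atlas,
            axis_d,
            hub_wiring,
        )
        motion = _motion_trace(rng, n_timepoints)
        pet = _generate_pet(
            rng,
            grid,
            atlas,
            ref_mask,
            is_case,
            axis_d.get("pet_mean", 0.0),
            targets,
            effect.noise_sd,
        )
        group = "ctrl" if labels[i] == 0 else "case"
        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{group}{i:03d}",
                bold=VolumeTimeSeries(bold, tr_seconds, mask.copy()),
                motion=motion,
                pet=pet,
            )
        )

    return CohortBundle(
        subjects=subjects,
        labels=labels,
        atlas=atlas,
        truth=effect,
        seed=seed,
        voxel_size_mm=voxel_size_mm,
        tr_seconds=tr_seconds,
    )


def save_cohort(bundle: CohortBundle, out_dir) -> None:
    """Write a cohort as NIfTI volumes, motion/labels TSVs and truth JSON."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = bundle.voxel_size_mm
    save_nifti_int(bundle.atlas.labels, out / "atlas.nii.gz", vs)
    if bundle.subjects:
        ref = bundle.subjects[0].pet.reference_mask.astype(np.int16)
        save_nifti_int(ref, out / "reference_mask.nii.gz", vs)
    for s in bundle.subjects:
        save_nifti(s.bold.data, out / f"{s.subject_id}_bold.nii.gz", vs)
        save_nifti(s.pet.data, out / f"{s.subject_id}_pet.nii.gz", vs)
        save_motion_tsv(s.motion, out / f"{s.subject_id}_motion.tsv")
    save_labels_tsv(bundle.subject_ids, bundle.labels, out / "labels.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {"seed": bundle.seed, "effect": bundle.truth.to_dict()}, fh, indent=2
        )
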