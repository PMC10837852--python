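"""Thin NIfTI / TSV readers and writers used by the CLI and cohort export."""

from __future__ import annotations

import numpy as np
import pandas as pd
import nibabel as nib

from .errors import InvalidArgumentError
from .prep import MotionTrace

MOTION_COLUMNS = ["tx", "ty", "tz", "rx", "ry", "rz"]


def save_nifti(data: np.ndarray, path, voxel_size_mm: float = 3.0) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def save_nifti_int(data: np.ndarray, path, voxel_size_mm: float = 3.0) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.int16), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj), voxel


def save_motion_tsv(m: MotionTrace, path) -> None:
    pd.DataFrame(m.params, columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)


def load_motion_tsv(path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f"motion TSV missing columns {missing}")
    return MotionTrace(df[MOTION_COLUMNS].to_numpy(float))


def save_labels_tsv(subject_ids, labels, path) -> None:
    pd.DataFrame({"subject_id": subject_ids, "group": np.asarray(labels, int)}).to_csv(
        path, sep="\t", index=False
    )


def load_labels_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["subject_id"].astype(str).tolist(), df["group"].to_numpy(int)
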