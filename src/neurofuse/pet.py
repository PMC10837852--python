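"""PET intensity normalisation.

Converts a 3D PET uptake volume into a standardised uptake value ratio
(SUVR) map by dividing every voxel by the mean signal of a reference region
(a cerebellar mask in whole-brain FDG studies).  SUVR removes global
between-subject scale (dose, weight, scanner gain), so the reference-region
mean is exactly 1 in every output map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, InvalidReferenceError
from .metrics import MetricMap

__all__ = ["PetVolume", "compute_suvr"]


@dataclass
class PetVolume:
    """A 3D PET intensity grid with brain and reference masks."""

    data: np.ndarray
    mask: np.ndarray
    reference_mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.reference_mask = np.asarray(self.reference_mask, dtype=bool)
        if self.data.ndim != 3:
            raise InvalidArgumentError("PET data must be 3D")
        if self.data.shape != self.mask.shape or self.data.shape != self.reference_mask.shape:
            raise InvalidArgumentError("mask shapes must match the data grid")
        if not self.reference_mask.any():
            raise InvalidArgumentError("reference_mask is empty")
        if (self.reference_mask & ~self.mask).any():
            raise InvalidArgumentError("reference_mask must lie within mask")
        if (self.data[self.mask] < 0).any():
            raise InvalidArgumentError("PET intensities must be non-negative")


def compute_suvr(p: PetVolume) -> MetricMap:
    """Standardised uptake value ratio map.

    SUVR(voxel) = intensity(voxel) / mean intensity over the reference
    region.  Invariant to global rescaling of the input volume.
    """
    ref_mean = p.data[p.reference_mask].mean()
    if ref_mean <= 0:
        raise InvalidReferenceError(
            f"reference region mean must be positive, got {ref_mean}"
        )
    values = np.zeros_like(p.data)
    values[p.mask] = p.data[p.mask] / ref_mean
    return MetricMap(values, "suvr", p.mask.copy())
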