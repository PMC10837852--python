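"""Temporal preprocessing of BOLD-like 4D time series.

Covers the steps the voxelwise metrics expect to run downstream of spatial
preprocessing: discarding initial volumes, nuisance (confound) regression,
band-pass filtering, framewise-displacement computation with a motion
exclusion rule, and Gaussian spatial smoothing.  Spatial steps such as slice
timing, realignment and template normalisation are out of scope: input data
are assumed already aligned on a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import DegenerateDesignError, InvalidArgumentError

__all__ = [
    "VolumeTimeSeries",
    "MotionTrace",
    "discard_initial_volumes",
    "regress_confounds",
    "bandpass_filter",
    "framewise_displacement",
    "check_exclusion",
    "gaussian_smooth",
    "fwhm_to_sigma",
]

#: Conversion factor between a Gaussian FWHM and its standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Gaussian sigma in voxel units for a kernel FWHM given in mm."""
    return fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm


@dataclass
class VolumeTimeSeries:
    """A 4D BOLD-like grid with its repetition time and brain mask.

    Parameters
    ----------
    data:
        ``(X, Y, Z, T)`` float array of signal intensities.
    tr_seconds:
        Repetition time, i.e. the sampling interval of the time axis.
    mask:
        ``(X, Y, Z)`` boolean brain mask; metrics only consider in-mask
        voxels.
    """

    data: np.ndarray
    tr_seconds: float
    mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise InvalidArgumentError("data must be 4D (X, Y, Z, T)")
        if self.data.shape[:3] != self.mask.shape:
            raise InvalidArgumentError("mask shape must match spatial grid")
        if self.n_timepoints < 2:
            raise InvalidArgumentError("need at least 2 time points")
        if self.tr_seconds <= 0:
            raise InvalidArgumentError("tr_seconds must be positive")
        if not self.mask.any():
            raise InvalidArgumentError("mask is empty")
        if not np.isfinite(self.data[self.mask]).all():
            raise InvalidArgumentError("non-finite values inside the mask")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    def masked_series(self) -> np.ndarray:
        """Return the in-mask voxel time series as a ``(V, T)`` matrix."""
        return self.data[self.mask]

    def with_masked_series(self, series: np.ndarray) -> "VolumeTimeSeries":
        """Rebuild a volume from a ``(V, T)`` matrix of in-mask series."""
        out = np.zeros(self.mask.shape + (series.shape[1],))
        out[self.mask] = series
        return VolumeTimeSeries(out, self.tr_seconds, self.mask.copy())


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters over time.

    ``params`` is ``(T, 6)``: three translations in mm followed by three
    rotations in radians.  ``fd`` holds the per-frame framewise displacement
    (Power convention) once computed.
    """

    params: np.ndarray
    fd: np.ndarray | None = field(default=None)
    mean_fd: float | None = field(default=None)

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise InvalidArgumentError("params must have shape (T, 6)")


def discard_initial_volumes(v: VolumeTimeSeries, k: int) -> VolumeTimeSeries:
    """Drop the first ``k`` volumes (steady-state magnetisation discard)."""
    if not 0 <= k < v.n_timepoints:
        raise InvalidArgumentError(
            f"k={k} must satisfy 0 <= k < T={v.n_timepoints}"
        )
    return VolumeTimeSeries(v.data[..., k:], v.tr_seconds, v.mask.copy())


def regress_confounds(
    v: VolumeTimeSeries, regressors: np.ndarray | None
) -> VolumeTimeSeries:
    """Voxelwise least-squares removal of nuisance regressors.

    An intercept column is always added, so an empty regressor set simply
    mean-centres every voxel.  The returned residuals are orthogonal to every
    design column.  The composition of the design (motion expansions, tissue
    signals, ...) is the caller's responsibility.
    """
    t = v.n_timepoints
    if regressors is None or np.size(regressors) == 0:
        design = np.ones((t, 1))
    else:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim != 2 or regressors.shape[0] != t:
            raise InvalidArgumentError(
                f"regressors must be (T={t}, p), got {regressors.shape}"
            )
        design = np.column_stack([np.ones(t), regressors])

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # Identify offending columns with a pivoted QR.
        from scipy.linalg import qr

        _, r, piv = qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = sorted(piv[np.flatnonzero(diag < tol)])
        # Column 0 of the design is the intercept; report regressor indices.
        bad_regressors = [c - 1 for c in bad]
        raise DegenerateDesignError(
            f"rank-deficient confound design; offending columns {bad_regressors}",
            columns=bad_regressors,
        )

    series = v.masked_series()  # (V, T)
    beta, *_ = np.linalg.lstsq(design, series.T, rcond=None)
    resid = series.T - design @ beta  # (T, V)
    return v.with_masked_series(resid.T)


def bandpass_filter(
    v: VolumeTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> VolumeTimeSeries:
    """Ideal (frequency-domain) band-pass filter after linear detrending.

    Frequency bins strictly outside ``[low_hz, high_hz]`` are zeroed, giving
    a sharp stopband akin to the ideal filters of common rs-fMRI toolboxes.
    """
    nyq = v.nyquist_hz
    if not 0 <= low_hz < high_hz:
        raise InvalidArgumentError("need 0 <= low_hz < high_hz")
    if high_hz > nyq + 1e-12:
        raise InvalidArgumentError(
            f"high_hz={high_hz} exceeds Nyquist {nyq:.4g} Hz"
        )
    series = v.masked_series()
    series = signal.detrend(series, axis=1, type="linear")
    spect = np.fft.rfft(series, axis=1)
    freqs = np.fft.rfftfreq(v.n_timepoints, d=v.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spect[:, ~keep] = 0.0
    filtered = np.fft.irfft(spect, n=v.n_timepoints, axis=1)
    return v.with_masked_series(filtered)


def framewise_displacement(
    m: MotionTrace, head_radius_mm: float = 50.0
) -> MotionTrace:
    """Power-style framewise displacement.

    FD[t] is the sum of absolute backward differences of the three
    translations plus the three rotation differences converted to arc length
    on a sphere of ``head_radius_mm``.  FD[0] is defined as 0.
    """
    if m.params.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 frames for FD")
    deltas = np.abs(np.diff(m.params, axis=0))
    fd_tail = deltas[:, :3].sum(axis=1) + head_radius_mm * deltas[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd_tail])
    return MotionTrace(m.params.copy(), fd=fd, mean_fd=float(fd.mean()))


def check_exclusion(
    m: MotionTrace, trans_limit_mm: float = 2.0, rot_limit_deg: float = 2.0
) -> bool:
    """Motion exclusion rule on the realignment parameter range.

    Returns True (exclude the subject) when any frame's absolute translation
    exceeds ``trans_limit_mm`` on any axis, or any absolute rotation exceeds
    ``rot_limit_deg`` on any axis.
    """
    trans = np.abs(m.params[:, :3])
    rot_deg = np.degrees(np.abs(m.params[:, 3:]))
    return bool((trans > trans_limit_mm).any() or (rot_deg > rot_limit_deg).any())


def gaussian_smooth(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float = 3.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Isotropic 3D Gaussian smoothing of a 3D map or 4D time series.

    Boundary handling is constant (zero) padding; when a mask is given the
    result is re-masked after convolution (convolve-then-remask contract).
    """
    if fwhm_mm < 0:
        raise InvalidArgumentError("fwhm_mm must be non-negative")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        out = volume.copy()
    else:
        sigma = fwhm_to_sigma(fwhm_mm, voxel_size_mm)
        sigmas = (sigma, sigma, sigma) + (0.0,) * (volume.ndim - 3)
        out = ndimage.gaussian_filter(volume, sigma=sigmas, mode="constant", cval=0.0)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        out = out * (mask if volume.ndim == 3 else mask[..., None])
    return out
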