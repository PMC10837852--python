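"""Voxelwise resting-state fMRI metrics.

Five complementary maps of spontaneous brain activity and connectivity:

- fALFF: fraction of spectral amplitude inside the 0.01-0.08 Hz band,
  a normalised measure of low-frequency fluctuation strength.
- ReHo: Kendall's coefficient of concordance (KCC, W) between a voxel and
  its 26 in-mask neighbours, a measure of local synchrony.
- DC (degree centrality): sum of suprathreshold (r > 0.25) whole-brain
  correlations per voxel, Fisher-z weighted by default.
- FCS (functional connectivity strength): mean Fisher-z correlation over
  suprathreshold (r > 0.2) pairs, normalised by total mask size.
- VMHC: Pearson correlation between a voxel and its mirror across the
  midsagittal plane (interhemispheric coupling).

Raw maps can be standardised either by within-mask z-scoring (fALFF, ReHo,
DC, FCS) or by the Fisher z-transform (correlation-valued maps, VMHC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .errors import InvalidArgumentError
from .prep import VolumeTimeSeries

__all__ = [
    "MetricParams",
    "MetricMap",
    "compute_falff",
    "compute_reho",
    "compute_dc",
    "compute_fcs",
    "compute_dc_fcs",
    "compute_vmhc",
    "standardize_map",
]


@dataclass(frozen=True)
class MetricParams:
    """Shared tunable parameters of the voxelwise metrics.

    ``low_hz``/``high_hz`` bound the low-frequency band; ``fcs_r0`` and
    ``dc_threshold`` are the correlation thresholds that prune weak,
    noise-dominated edges; ``reho_neighbors`` selects the neighbourhood
    system (6, 18 or 26 face/edge/corner neighbours); ``r_clip`` keeps
    atanh finite for (numerically) perfect correlations.
    """

    low_hz: float = 0.01
    high_hz: float = 0.08
    fcs_r0: float = 0.2
    dc_threshold: float = 0.25
    reho_neighbors: int = 26
    fwhm_mm: float = 6.0
    r_clip: float = 1.0 - 1e-7

    def __post_init__(self):
        if not 0 < self.fcs_r0 < 1:
            raise InvalidArgumentError("fcs_r0 must lie in (0, 1)")
        if not 0 < self.dc_threshold <= 1:
            raise InvalidArgumentError("dc_threshold must lie in (0, 1]")
        if self.reho_neighbors not in (6, 18, 26):
            raise InvalidArgumentError("reho_neighbors must be 6, 18 or 26")


@dataclass
class MetricMap:
    """A 3D voxelwise metric map with bookkeeping flags.

    ``degenerate`` marks voxels whose value required a fallback definition
    (e.g. all-zero time series); ``missing`` marks voxels where the metric
    is undefined (e.g. VMHC with the mirror voxel outside the mask) — those
    are excluded from ROI averaging.
    """

    values: np.ndarray
    metric_name: str
    mask: np.ndarray
    standardized: bool = False
    degenerate: np.ndarray = field(default=None)
    missing: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.degenerate is None:
            self.degenerate = np.zeros_like(self.mask)
        if self.missing is None:
            self.missing = np.zeros_like(self.mask)
        if not np.isfinite(self.values[self.mask]).all():
            raise InvalidArgumentError("non-finite metric values inside mask")

    @property
    def valid(self) -> np.ndarray:
        """In-mask voxels carrying a usable value."""
        return self.mask & ~self.missing


def _neighbor_kernel(k: int) -> np.ndarray:
    """3x3x3 structuring element for the K-neighbour system (centre included)."""
    offsets = np.abs(np.indices((3, 3, 3)) - 1).sum(axis=0)
    if k == 6:
        return offsets <= 1
    if k == 18:
        return offsets <= 2
    return np.ones((3, 3, 3), dtype=bool)


def compute_falff(
    v: VolumeTimeSeries,
    params: MetricParams = MetricParams(),
    power_ratio: bool = False,
) -> MetricMap:
    """Fractional amplitude of low-frequency fluctuations.

    Expects an *unfiltered* series (the ratio must see the whole spectrum).
    Per voxel the one-sided FFT amplitude spectrum is summed over the
    low-frequency band and divided by the sum over all positive frequencies
    up to Nyquist; the DC bin is excluded so the ratio is insensitive to the
    signal mean.  ``power_ratio=True`` uses squared amplitudes instead (the
    literal power-ratio reading).
    """
    if v.n_timepoints < 32:
        raise InvalidArgumentError("fALFF needs at least 32 time points")
    series = v.masked_series()
    series = series - series.mean(axis=1, keepdims=True)
    amp = np.abs(np.fft.rfft(series, axis=1))
    if power_ratio:
        amp = amp**2
    freqs = np.fft.rfftfreq(v.n_timepoints, d=v.tr_seconds)
    band = (freqs >= params.low_hz) & (freqs <= params.high_hz)
    full = freqs > 0
    num = amp[:, band].sum(axis=1)
    den = amp[:, full].sum(axis=1)
    degenerate = den <= 0
    vals = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))

    values = np.zeros(v.grid_shape)
    values[v.mask] = vals
    deg = np.zeros(v.grid_shape, dtype=bool)
    deg[v.mask] = degenerate
    return MetricMap(values, "falff", v.mask.copy(), degenerate=deg)


def compute_reho(
    v: VolumeTimeSeries, params: MetricParams = MetricParams()
) -> MetricMap:
    """Regional homogeneity via Kendall's coefficient of concordance.

    For each voxel the raters are the voxel itself plus its in-mask
    neighbours (K' <= 27 for the 26-neighbour system).  With R_i the sum of
    the raters' time-point ranks,

        W = 12 * sum_i (R_i - mean(R))^2 / (K'^2 (n^3 - n)),

    where n is the number of time points.  Ranks use midranks for ties; the
    tie-correction term is omitted (a small downward bias for heavily tied
    data).  Border voxels use the available in-mask raters rather than being
    discarded; a voxel with no in-mask neighbour degenerates to W = 1 and is
    flagged.
    """
    n = v.n_timepoints
    if n < 3:
        raise InvalidArgumentError("ReHo needs at least 3 time points")
    series = v.masked_series()
    ranks = rankdata(series, axis=1, method="average")

    rank_vol = np.zeros(v.grid_shape + (n,))
    rank_vol[v.mask] = ranks
    kernel = _neighbor_kernel(params.reho_neighbors).astype(float)

    # Sum of neighbour ranks per time point and in-mask rater count.
    rank_sum = ndimage.correlate(
        rank_vol, kernel[..., None], mode="constant", cval=0.0
    )
    k_count = ndimage.correlate(
        v.mask.astype(float), kernel, mode="constant", cval=0.0
    )

    r = rank_sum[v.mask]  # (V, n): R_i per time point
    k = k_count[v.mask]  # (V,)
    dev = r - r.mean(axis=1, keepdims=True)
    s = (dev**2).sum(axis=1)
    w = 12.0 * s / (k**2 * (n**3 - n))

    values = np.zeros(v.grid_shape)
    values[v.mask] = np.clip(w, 0.0, 1.0)
    deg = np.zeros(v.grid_shape, dtype=bool)
    deg[v.mask] = k <= 1
    return MetricMap(values, "reho", v.mask.copy(), degenerate=deg)


def _standardized_series(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean, unit-norm rows; constant rows become zero (flagged)."""
    centered = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms <= 0
    safe = np.where(constant, 1.0, norms)
    return centered / safe[:, None], constant


def compute_dc_fcs(
    v: VolumeTimeSeries,
    params: MetricParams = MetricParams(),
    weighted: bool = True,
    chunk: int = 1024,
) -> tuple[MetricMap, MetricMap]:
    """Degree centrality and connectivity strength from one correlation pass.

    The full voxel-by-voxel Pearson correlation matrix is traversed in row
    chunks.  DC sums Fisher-z weights (or edge counts in binary mode) over
    edges with r > ``dc_threshold``; FCS averages Fisher-z weights over
    edges with r > ``fcs_r0``, normalised by the total in-mask voxel count.
    Constant time series correlate 0 with everything and are flagged.
    """
    series = v.masked_series()
    nvox = series.shape[0]
    if nvox < 2:
        raise InvalidArgumentError("need at least 2 in-mask voxels")
    z, constant = _standardized_series(series)

    dc = np.zeros(nvox)
    fcs = np.zeros(nvox)
    for start in range(0, nvox, chunk):
        stop = min(start + chunk, nvox)
        r = z[start:stop] @ z.T  # (chunk, V)
        np.clip(r, -params.r_clip, params.r_clip, out=r)
        # remove self-edges
        idx = np.arange(start, stop)
        r[np.arange(stop - start), idx] = 0.0
        zr = np.arctanh(r)
        dc_edges = r > params.dc_threshold
        fcs_edges = r > params.fcs_r0
        if weighted:
            dc[start:stop] = np.where(dc_edges, zr, 0.0).sum(axis=1)
        else:
            dc[start:stop] = dc_edges.sum(axis=1)
        fcs[start:stop] = np.where(fcs_edges, zr, 0.0).sum(axis=1) / nvox

    dc[constant] = 0.0
    fcs[constant] = 0.0

    def to_map(vals, name):
        values = np.zeros(v.grid_shape)
        values[v.mask] = vals
        deg = np.zeros(v.grid_shape, dtype=bool)
        deg[v.mask] = constant
        return MetricMap(values, name, v.mask.copy(), degenerate=deg)

    return to_map(dc, "dc"), to_map(fcs, "fcs")


def compute_dc(
    v: VolumeTimeSeries,
    params: MetricParams = MetricParams(),
    weighted: bool = True,
) -> MetricMap:
    """Voxelwise degree centrality (see :func:`compute_dc_fcs`)."""
    dc, _ = compute_dc_fcs(v, params, weighted=weighted)
    return dc


def compute_fcs(
    v: VolumeTimeSeries, params: MetricParams = MetricParams()
) -> MetricMap:
    """Voxelwise functional connectivity strength (see :func:`compute_dc_fcs`)."""
    _, fcs = compute_dc_fcs(v, params)
    return fcs


def compute_vmhc(v: VolumeTimeSeries, mirror_axis: int = 0) -> MetricMap:
    """Voxel-mirrored homotopic connectivity.

    Pearson correlation between each voxel's time series and that of its
    mirror across the mid-plane of ``mirror_axis`` (which must have even
    length so every voxel has an exact mirror).  Voxels whose mirror falls
    outside the mask are flagged missing.
    """
    dim = v.grid_shape[mirror_axis]
    if dim % 2 != 0:
        raise InvalidArgumentError(
            f"grid axis {mirror_axis} must be even for mirroring, got {dim}"
        )
    flipped = np.flip(v.data, axis=mirror_axis)
    flipped_mask = np.flip(v.mask, axis=mirror_axis)
    valid = v.mask & flipped_mask

    a = v.data[valid]
    b = flipped[valid]
    za, const_a = _standardized_series(a)
    zb, const_b = _standardized_series(b)
    r = (za * zb).sum(axis=1)
    const = const_a | const_b
    r[const] = 0.0
    r = np.clip(r, -1.0, 1.0)

    values = np.zeros(v.grid_shape)
    values[valid] = r
    missing = v.mask & ~valid
    deg = np.zeros(v.grid_shape, dtype=bool)
    deg[valid] = const
    return MetricMap(values, "vmhc", v.mask.copy(), degenerate=deg, missing=missing)


def standardize_map(m: MetricMap, method: str = "mask_zscore") -> MetricMap:
    """Standardise a metric map for group-level comparability.

    ``mask_zscore`` subtracts the in-mask mean and divides by the in-mask SD
    (the toolbox-style z-map convention for fALFF/ReHo/DC).  ``fisher_z``
    applies atanh and is only valid for correlation-valued maps.
    """
    if method not in ("mask_zscore", "fisher_z"):
        raise InvalidArgumentError(f"unknown standardization method {method!r}")
    valid = m.valid
    vals = m.values.copy()
    degenerate = m.degenerate.copy()
    if method == "fisher_z":
        if np.abs(vals[valid]).max(initial=0.0) > 1.0:
            raise InvalidArgumentError(
                "fisher_z requires values in [-1, 1] (correlation-valued map)"
            )
        clip = 1.0 - 1e-7
        vals[valid] = np.arctanh(np.clip(vals[valid], -clip, clip))
    else:
        mean = vals[valid].mean()
        sd = vals[valid].std()
        if sd <= 0:
            vals[valid] = 0.0
            degenerate |= valid
        else:
            vals[valid] = (vals[valid] - mean) / sd
    return MetricMap(
        vals,
        m.metric_name,
        m.mask.copy(),
        standardized=True,
        degenerate=degenerate,
        missing=m.missing.copy(),
    )
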