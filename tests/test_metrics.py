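import numpy as np
import pytest
from scipy.stats import rankdata

from neurofuse import (
    InvalidArgumentError,
    MetricParams,
    VolumeTimeSeries,
    compute_dc,
    compute_dc_fcs,
    compute_falff,
    compute_fcs,
    compute_reho,
    compute_vmhc,
    standardize_map,
)


def brute_force_kcc(series_block: np.ndarray) -> float:
    """Direct Kendall's W of a raters x timepoints block (midranks, no tie
    correction): W = 12 * sum_i (R_i - mean R)^2 / (K^2 (n^3 - n))."""
    k, n = series_block.shape
    ranks = np.vstack([rankdata(row) for row in series_block])
    r_i = ranks.sum(axis=0)
    s = ((r_i - r_i.mean()) ** 2).sum()
    return 12.0 * s / (k**2 * (n**3 - n))


def brute_force_fcs(series: np.ndarray, r0: float, r_clip: float) -> np.ndarray:
    """Double-loop mean suprathreshold Fisher-z connectivity per voxel."""
    nvox = series.shape[0]
    out = np.zeros(nvox)
    for i in range(nvox):
        acc = 0.0
        for j in range(nvox):
            if i == j:
                continue
            r = np.corrcoef(series[i], series[j])[0, 1]
            if r > r0:
                acc += np.arctanh(min(r, r_clip))
        out[i] = acc / nvox
    return out


def _volume_from_series(series, tr=2.0):
    """Pack a (V, T) matrix into a Vx1x1 volume with a full mask."""
    v = series.shape[0]
    data = series.reshape(v, 1, 1, -1)
    return VolumeTimeSeries(data, tr, np.ones((v, 1, 1), bool))


class TestFalff:
    def _sinusoid(self, freq, n_t=256, tr=2.0, rng=None):
        # snap to the nearest FFT bin so spectral leakage does not blur
        # the in-band/out-of-band contrast the ratio is meant to expose
        freq = round(freq * n_t * tr) / (n_t * tr)
        t = np.arange(n_t) * tr
        sig = np.sin(2 * np.pi * freq * t)
        if rng is not None:
            # keep additive noise tiny: summed *amplitude* across all bins
            # grows with the bin count, so even small noise lifts the
            # out-of-band amplitude floor appreciably
            sig = sig + 1e-3 * rng.standard_normal(n_t)
        return sig

    def test_in_band_sinusoid_near_one(self, rng):
        series = np.vstack([self._sinusoid(0.04, rng=rng) for _ in range(4)])
        m = compute_falff(_volume_from_series(series))
        assert (m.values[m.mask] >= 0.95).all()

    def test_out_of_band_sinusoid_near_zero(self, rng):
        series = np.vstack([self._sinusoid(0.20, rng=rng) for _ in range(4)])
        m = compute_falff(_volume_from_series(series))
        assert (m.values[m.mask] <= 0.05).all()

    def test_white_noise_matches_band_fraction(self, rng):
        n_t = 1024
        series = rng.standard_normal((100, n_t))
        m = compute_falff(_volume_from_series(series))
        freqs = np.fft.rfftfreq(n_t, d=2.0)
        frac = ((freqs >= 0.01) & (freqs <= 0.08)).sum() / (freqs > 0).sum()
        assert m.values[m.mask].mean() == pytest.approx(frac, abs=0.05)

    def test_scale_invariance(self, rng):
        series = rng.standard_normal((5, 64))
        a = compute_falff(_volume_from_series(series))
        b = compute_falff(_volume_from_series(3.7 * series))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_all_zero_voxel_flagged_degenerate(self, rng):
        series = rng.standard_normal((3, 64))
        series[1] = 0.0
        m = compute_falff(_volume_from_series(series))
        assert m.values[1, 0, 0] == 0.0
        assert m.degenerate[1, 0, 0]
        assert not m.degenerate[0, 0, 0]


class TestReho:
    def test_identical_series_give_unit_w(self, rng):
        base = rng.standard_normal(20)
        data = np.broadcast_to(base, (3, 3, 3, 20)).copy()
        v = VolumeTimeSeries(data, 2.0, np.ones((3, 3, 3), bool))
        m = compute_reho(v)
        np.testing.assert_allclose(m.values[m.mask], 1.0, atol=1e-12)

    def test_reversed_ranks_give_zero_w(self):
        # two-voxel mask with exactly opposite monotone series
        data = np.zeros((2, 1, 1, 10))
        data[0, 0, 0] = np.arange(10)
        data[1, 0, 0] = -np.arange(10)
        mask = np.ones((2, 1, 1), bool)
        m = compute_reho(VolumeTimeSeries(data, 2.0, mask))
        np.testing.assert_allclose(m.values[mask], 0.0, atol=1e-12)

    def test_matches_brute_force_on_random_volume(self, rng):
        shape = (6, 6, 6)
        n_t = 20
        data = rng.standard_normal(shape + (n_t,))
        mask = np.ones(shape, bool)
        m = compute_reho(VolumeTimeSeries(data, 2.0, mask))
        for voxel in [(0, 0, 0), (3, 3, 3), (5, 2, 4), (1, 5, 0)]:
            x, y, z = voxel
            block = []
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        i, j, k = x + dx, y + dy, z + dz
                        if 0 <= i < 6 and 0 <= j < 6 and 0 <= k < 6:
                            block.append(data[i, j, k])
            expected = brute_force_kcc(np.vstack(block))
            assert m.values[voxel] == pytest.approx(expected, abs=1e-10)

    def test_isolated_voxel_flagged(self, rng):
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = True
        mask[4, 4, 4] = True
        data = rng.standard_normal((5, 5, 5, 12))
        m = compute_reho(VolumeTimeSeries(data, 2.0, mask))
        assert m.degenerate[0, 0, 0]
        assert m.values[0, 0, 0] == pytest.approx(1.0)


class TestDegreeCentrality:
    def test_clique_and_isolates(self, rng):
        n_t = 400
        shared = np.sin(2 * np.pi * 0.04 * np.arange(n_t) * 2.0)
        series = np.vstack(
            [
                shared + 0.05 * rng.standard_normal(n_t),
                shared + 0.05 * rng.standard_normal(n_t),
                shared + 0.05 * rng.standard_normal(n_t),
                rng.standard_normal(n_t),
                rng.standard_normal(n_t),
            ]
        )
        v = _volume_from_series(series)
        m = compute_dc(v)
        # brute-force pairwise oracle
        params = MetricParams()
        expected = np.zeros(5)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                r = np.corrcoef(series[i], series[j])[0, 1]
                if r > params.dc_threshold:
                    expected[i] += np.arctanh(min(r, params.r_clip))
        np.testing.assert_allclose(m.values[:, 0, 0], expected, atol=1e-10)
        assert m.values[0, 0, 0] > 1.0
        assert m.values[3, 0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_binary_mode_counts_clique_degree(self, rng):
        n_t = 100
        shared = rng.standard_normal(n_t)
        series = np.vstack([shared + 1e-3 * rng.standard_normal(n_t) for _ in range(4)])
        m = compute_dc(_volume_from_series(series), weighted=False)
        np.testing.assert_allclose(m.values[:, 0, 0], 3.0)

    def test_threshold_one_gives_zero(self, rng):
        series = rng.standard_normal((6, 50))
        params = MetricParams(dc_threshold=1.0)
        m = compute_dc(_volume_from_series(series), params)
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_constant_voxel_has_no_edges(self, rng):
        series = rng.standard_normal((4, 50))
        series[2] = 5.0
        m = compute_dc(_volume_from_series(series))
        assert m.values[2, 0, 0] == 0.0
        assert m.degenerate[2, 0, 0]


class TestFcs:
    def test_matches_double_loop_oracle(self, rng):
        series = rng.standard_normal((10, 40))
        params = MetricParams()
        m = compute_fcs(_volume_from_series(series), params)
        expected = brute_force_fcs(series, params.fcs_r0, params.r_clip)
        np.testing.assert_allclose(m.values[:, 0, 0], expected, atol=1e-10)

    def test_uncorrelated_voxel_is_zero(self, rng):
        n_t = 30
        series = rng.standard_normal((5, n_t))
        r = np.corrcoef(series)
        np.fill_diagonal(r, 0.0)
        target = int(np.abs(r).max(axis=1).argmin())
        if np.abs(r[target]).max() < 0.2:
            m = compute_fcs(_volume_from_series(series))
            assert m.values[target, 0, 0] == 0.0

    def test_monotone_in_threshold(self, rng):
        series = rng.standard_normal((8, 60))
        lo = compute_fcs(_volume_from_series(series), MetricParams(fcs_r0=0.05))
        hi = compute_fcs(_volume_from_series(series), MetricParams(fcs_r0=0.2))
        assert (lo.values >= hi.values - 1e-12).all()

    def test_rescaling_invariance(self, rng):
        series = rng.standard_normal((6, 50))
        scaled = series * rng.uniform(0.5, 3.0, size=(6, 1)) + rng.normal(
            0, 2, size=(6, 1)
        )
        a = compute_fcs(_volume_from_series(series))
        b = compute_fcs(_volume_from_series(scaled))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


class TestVmhc:
    def test_mirrored_volume_gives_unit_correlation(self, rng):
        half = rng.standard_normal((3, 4, 4, 30))
        data = np.concatenate([half, half[::-1]], axis=0)
        v = VolumeTimeSeries(data, 2.0, np.ones((6, 4, 4), bool))
        m = compute_vmhc(v)
        np.testing.assert_allclose(m.values[m.valid], 1.0, atol=1e-10)

    def test_independent_halves_near_zero(self, rng):
        data = rng.standard_normal((4, 3, 3, 200))
        v = VolumeTimeSeries(data, 2.0, np.ones((4, 3, 3), bool))
        m = compute_vmhc(v)
        assert np.abs(m.values[m.valid]).mean() <= 0.15

    def test_symmetry_under_mirroring(self, rng):
        data = rng.standard_normal((4, 3, 3, 40))
        v = VolumeTimeSeries(data, 2.0, np.ones((4, 3, 3), bool))
        m = compute_vmhc(v)
        np.testing.assert_allclose(m.values, m.values[::-1], atol=1e-12)

    def test_mirror_outside_mask_flagged_missing(self, rng):
        mask = np.ones((4, 3, 3), bool)
        mask[3] = False  # kill the mirror of x=0
        data = rng.standard_normal((4, 3, 3, 20))
        m = compute_vmhc(VolumeTimeSeries(data, 2.0, mask))
        assert m.missing[0].all()
        assert not m.valid[0].any()

    def test_odd_axis_rejected(self, rng):
        data = rng.standard_normal((5, 2, 2, 20))
        with pytest.raises(InvalidArgumentError):
            compute_vmhc(VolumeTimeSeries(data, 2.0, np.ones((5, 2, 2), bool)))


class TestStandardizeMap:
    def test_mask_zscore_contract(self, rng):
        m = compute_falff(_volume_from_series(rng.standard_normal((30, 64))))
        z = standardize_map(m, "mask_zscore")
        assert z.standardized
        assert z.values[z.mask].mean() == pytest.approx(0.0, abs=1e-10)
        assert z.values[z.mask].std() == pytest.approx(1.0, abs=1e-10)

    def test_fisher_z_closed_form(self, rng):
        data = rng.standard_normal((4, 3, 3, 40))
        m = compute_vmhc(VolumeTimeSeries(data, 2.0, np.ones((4, 3, 3), bool)))
        m.values[m.mask] = 0.5
        z = standardize_map(m, "fisher_z")
        assert z.values[z.mask][0] == pytest.approx(np.arctanh(0.5))

    def test_fisher_z_rejects_out_of_range(self, rng):
        m = compute_dc(_volume_from_series(rng.standard_normal((4, 50))))
        m.values[m.mask] += 2.0
        with pytest.raises(InvalidArgumentError):
            standardize_map(m, "fisher_z")

    def test_constant_map_flagged_degenerate(self, rng):
        m = compute_falff(_volume_from_series(rng.standard_normal((5, 64))))
        m.values[m.mask] = 0.7
        z = standardize_map(m, "mask_zscore")
        np.testing.assert_array_equal(z.values[z.mask], 0.0)
        assert z.degenerate[z.mask].all()


def test_dc_fcs_shared_pass_agrees_with_separate_calls(rng):
    series = rng.standard_normal((12, 40))
    v = _volume_from_series(series)
    dc, fcs = compute_dc_fcs(v)
    np.testing.assert_array_equal(dc.values, compute_dc(v).values)
    np.testing.assert_array_equal(fcs.values, compute_fcs(v).values)


def test_metrics_deterministic(rng):
    series = rng.standard_normal((8, 48))
    v = _volume_from_series(series)
    for fn in (compute_falff, compute_reho, compute_dc, compute_fcs):
        a, b = fn(v), fn(v)
        np.testing.assert_array_equal(a.values, b.values)
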