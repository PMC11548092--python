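"""MAV/RMS/MPF/MF against loop oracles and closed forms; normalization."""
import numpy as np
import pytest

from semgrec.features import (FeatureMatrix, PSDEstimate,
                              estimate_psd, featurize, mav, mf, mpf, normalize,
                              rms)
from semgrec.segmentation import WindowDataset, Window


def _point_mass(freq, grid_max=500.0, n=501, weight=1.0):
    freqs = np.linspace(0, grid_max, n)
    power = np.zeros(n)
    power[np.argmin(np.abs(freqs - freq))] = weight
    return freqs, power


class TestTimeDomain:
    def test_constant_and_direct_arithmetic(self):
        assert mav(np.full(10, -2.0)) == 2.0
        assert mav([1, -1, 2, -2]) == 1.5
        assert rms([1, -1, 1, -1]) == 1.0
        assert rms(np.zeros(16)) == 0.0

    def test_loop_oracle_500_series(self, rng):
        for _ in range(500):
            x = rng.normal(size=rng.integers(1, 200)) * rng.uniform(0.1, 10)
            n = x.size
            mav_loop = sum(abs(v) for v in x) / n
            rms_loop = (sum(v * v for v in x) / n) ** 0.5
            assert abs(mav(x) - mav_loop) < 1e-12
            assert abs(rms(x) - rms_loop) < 1e-12

    def test_mav_le_rms_power_mean_inequality(self, rng):
        for _ in range(500):
            x = rng.normal(size=rng.integers(2, 100))
            assert mav(x) <= rms(x) + 1e-15

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mav([])
        with pytest.raises(ValueError):
            rms([])


class TestPSD:
    def test_sinusoid_peak_location(self):
        t = np.arange(4000) / 1000.0
        psd = estimate_psd(np.sin(2 * np.pi * 120 * t), fs=1000.0)
        peak = psd.freqs[np.argmax(psd.power)]
        bin_width = psd.freqs[1] - psd.freqs[0]
        assert abs(peak - 120.0) <= bin_width

    def test_parseval_white_noise(self):
        ratios = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(4096)
            psd = estimate_psd(x, fs=1000.0)
            total = np.trapezoid(psd.power, psd.freqs)
            ratios.append(total / x.var())
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_zero_series_zero_power(self):
        psd = estimate_psd(np.zeros(1024), fs=1000.0)
        assert np.all(psd.power == 0)

    def test_too_short(self):
        with pytest.raises(ValueError, match="shorter"):
            estimate_psd(np.zeros(100), fs=1000.0)


class TestSpectralMoments:
    def test_point_mass(self):
        psd = PSDEstimate(*_point_mass(100.0))
        assert mpf(psd) == pytest.approx(100.0, abs=1e-9)
        assert mf(psd) == pytest.approx(100.0, abs=1e-9)

    def test_flat_spectrum(self):
        freqs = np.linspace(0, 500, 501)
        psd = PSDEstimate(freqs, np.ones(501))
        half_bin = 0.5
        assert abs(mpf(psd) - 250.0) <= half_bin
        assert abs(mf(psd) - 250.0) <= half_bin

    def test_two_equal_masses_symmetric(self):
        freqs, p1 = _point_mass(50.0)
        _, p2 = _point_mass(150.0)
        assert mpf(PSDEstimate(freqs, p1 + p2)) == pytest.approx(100.0, abs=1e-9)

    def test_unequal_masses_median_at_heavier(self):
        freqs, p1 = _point_mass(50.0, weight=1.0)
        _, p2 = _point_mass(200.0, weight=3.0)
        assert mf(PSDEstimate(freqs, p1 + p2)) == pytest.approx(200.0)

    def test_moments_within_grid(self, rng):
        for _ in range(50):
            freqs = np.linspace(0, 500, 257)
            psd = PSDEstimate(freqs, rng.uniform(0, 1, 257))
            assert freqs[0] <= mpf(psd) <= freqs[-1]
            assert freqs[0] <= mf(psd) <= freqs[-1]

    def test_zero_power_rejected(self):
        psd = PSDEstimate(np.linspace(0, 500, 11), np.zeros(11))
        with pytest.raises(ValueError):
            mpf(psd)
        with pytest.raises(ValueError):
            mf(psd)


class TestFeaturize:
    def _ds(self, n=1, rng=None):
        rng = rng or np.random.default_rng(0)
        wins = [Window(samples=rng.normal(size=(7, 1024)), label="walk")
                for _ in range(n)]
        return WindowDataset(windows=wins)

    def test_shape_and_column_order(self):
        fm = featurize(self._ds(1), fs=1000.0)
        assert fm.values.shape == (1, 28)
        assert fm.columns[:4] == ["ch1_mav", "ch1_rms", "ch1_mpf", "ch1_mf"]
        assert fm.columns[4] == "ch2_mav"

    def test_duplicate_window_duplicates_row(self):
        ds = self._ds(1)
        ds2 = WindowDataset(windows=[ds.windows[0], ds.windows[0]])
        fm = featurize(ds2, fs=1000.0)
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_scaling_homogeneity(self):
        ds = self._ds(1)
        scaled = WindowDataset(windows=[Window(samples=2 * ds.windows[0].samples,
                                               label="walk")])
        a = featurize(ds, fs=1000.0).values[0]
        b = featurize(scaled, fs=1000.0).values[0]
        for c in range(7):
            assert b[4 * c] == pytest.approx(2 * a[4 * c], rel=1e-9)       # MAV
            assert b[4 * c + 1] == pytest.approx(2 * a[4 * c + 1], rel=1e-9)  # RMS
            assert b[4 * c + 2] == pytest.approx(a[4 * c + 2], abs=1e-9)   # MPF
            assert b[4 * c + 3] == pytest.approx(a[4 * c + 3], abs=1e-9)   # MF

    def test_window_permutation_permutes_rows(self, rng):
        ds = self._ds(5, rng)
        fm = featurize(ds, fs=1000.0)
        perm = [4, 2, 0, 3, 1]
        ds_p = WindowDataset(windows=[ds.windows[i] for i in perm])
        fm_p = featurize(ds_p, fs=1000.0)
        assert np.array_equal(fm_p.values, fm.values[perm])


class TestNormalize:
    def _fm(self, rng):
        vals = rng.normal(size=(40, 6)) * rng.uniform(0.5, 5, 6) + rng.normal(0, 3, 6)
        return FeatureMatrix(values=vals, labels=np.zeros(40, dtype=int),
                             columns=[f"c{i}" for i in range(6)])

    def test_fit_on_all_standardizes(self, rng):
        out = normalize(self._fm(rng))
        assert np.allclose(out.values.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(out.values.std(axis=0), 1, atol=1e-9)

    def test_heldout_transform_hand_check(self, rng):
        fm = self._fm(rng)
        fit_idx = np.arange(30)
        out = normalize(fm, fit_on=fit_idx)
        mean = fm.values[fit_idx].mean(axis=0)
        sd = fm.values[fit_idx].std(axis=0)
        r = 35
        assert np.allclose(out.values[r], (fm.values[r] - mean) / sd, atol=1e-12)
        assert np.allclose(out.norm_params["mean"], mean)

    def test_idempotent_params(self, rng):
        fm = self._fm(rng)
        a = normalize(fm, fit_on=np.arange(20)).values
        b = normalize(fm, fit_on=np.arange(20)).values
        assert np.array_equal(a, b)

    def test_zero_variance_column_named(self, rng):
        fm = self._fm(rng)
        fm.values[:, 3] = 7.0
        with pytest.raises(ValueError, match="c3"):
            normalize(fm)
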