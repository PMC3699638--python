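import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsebold import BoldSeries, PulseTrace, TissueMasks, ValidationError
from pulsebold.metrics import (amplitude_spectrum, cardiac_frequency,
                               cardiac_pulsatility_map, cumulative_motion,
                               sigma_physio_map, thermal_variance,
                               tissue_summary)
from pulsebold.preprocess import thermal_roi


def brute_force_dft_amplitude(course, tr):
    """Independent oracle: direct O(n^2) DFT with one-sided scaling."""
    n = len(course)
    n_bins = n // 2 + 1
    amps = np.empty(n_bins)
    for k in range(n_bins):
        c = np.sum(course * np.exp(-2j * np.pi * k * np.arange(n) / n))
        scale = 1.0 / n if (k == 0 or (n % 2 == 0 and k == n_bins - 1)) else 2.0 / n
        amps[k] = np.abs(c) * scale
    return np.fft.rfftfreq(n, d=tr), amps


class TestAmplitudeSpectrum:
    def test_constant_course_has_no_ac_power(self):
        spec = amplitude_spectrum(np.full(64, 7.0), 0.25)
        assert spec.amplitude[0] == pytest.approx(7.0)
        assert np.allclose(spec.amplitude[1:], 0.0, atol=1e-12)

    def test_on_bin_sinusoid_reads_its_amplitude(self):
        """100 + 2 sin(2pi t): bin spacing 0.008 Hz puts 1.0 Hz on bin 125."""
        n, tr = 500, 0.25
        t = np.arange(n) * tr
        spec = amplitude_spectrum(100.0 + 2.0 * np.sin(2 * np.pi * 1.0 * t), tr)
        assert spec.df_hz == pytest.approx(0.008)
        k = np.argmin(np.abs(spec.freqs_hz - 1.0))
        assert spec.freqs_hz[k] == pytest.approx(1.0)
        assert spec.amplitude[k] == pytest.approx(2.0, rel=1e-9)
        others = np.delete(spec.amplitude, [0, k])
        assert np.all(others < 1e-9)

    @pytest.mark.parametrize("n", [16, 33, 64])
    def test_matches_brute_force_dft(self, n, rng):
        course = rng.normal(10, 3, size=n)
        spec = amplitude_spectrum(course, 0.25)
        freqs, amps = brute_force_dft_amplitude(course, 0.25)
        assert np.allclose(spec.freqs_hz, freqs, rtol=1e-12)
        assert np.allclose(spec.amplitude, amps, rtol=1e-10, atol=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), n=st.sampled_from([32, 100, 127, 500]))
    def test_parseval_identity(self, seed, n):
        """Unwinding the one-sided scaling recovers mean power exactly."""
        course = np.random.default_rng(seed).normal(5, 2, size=n)
        spec = amplitude_spectrum(course, 0.25)
        power = spec.amplitude.copy() ** 2
        interior = np.ones(len(power), dtype=bool)
        interior[0] = False
        if n % 2 == 0:
            interior[-1] = False
        total = power[~interior].sum() + (power[interior] / 2).sum()
        assert total == pytest.approx(np.mean(course ** 2), rel=1e-8)

    def test_too_short_course_rejected(self):
        with pytest.raises(ValidationError):
            amplitude_spectrum(np.ones(3), 0.25)


class TestThermalVariance:
    def test_zero_for_constant_roi(self, flat_series):
        roi = thermal_roi(flat_series, None, extent_voxels=(4, 4),
                          corner_policy="fixed")
        data = np.zeros_like(flat_series.data)
        series = BoldSeries(data=data, tr_seconds=0.25)
        assert thermal_variance(series, roi) == 0.0

    def test_recovers_population_variance(self, rng):
        """Oracle: the generator's population variance (sigma = 5)."""
        data = rng.normal(0.0, 5.0, size=(16, 16, 3, 500))
        series = BoldSeries(data=data, tr_seconds=0.25)
        roi = thermal_roi(series, None, extent_voxels=(8, 8),
                          corner_policy="fixed")
        assert roi.n_voxels == 192
        assert thermal_variance(series, roi) == pytest.approx(25.0, rel=0.10)

    def test_mean_invariance(self, rng):
        noise = rng.normal(0.0, 5.0, size=(8, 8, 2, 200))
        s0 = BoldSeries(data=noise, tr_seconds=0.25)
        s1 = BoldSeries(data=noise + 1000.0, tr_seconds=0.25)
        roi = thermal_roi(s0, None, extent_voxels=(4, 4), corner_policy="fixed")
        assert thermal_variance(s0, roi) == pytest.approx(
            thermal_variance(s1, roi), rel=1e-10)


class TestSigmaPhysio:
    def _series_with_exact_variance(self, mask, var, mean, n=500, rng=None):
        rng = rng or np.random.default_rng(0)
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std(ddof=1)     # sample var exactly 1
        course = mean + np.sqrt(var) * z
        data = np.zeros(mask.shape + (n,))
        data[mask] = course
        return BoldSeries(data=data, tr_seconds=0.25)

    def test_square_summation_closed_form(self):
        """Variance 25, thermal 9, mean 100 -> sqrt(16) = 4% of the mean."""
        mask = np.zeros((4, 4, 1), dtype=bool)
        mask[1, 1, 0] = True
        series = self._series_with_exact_variance(mask, 25.0, 100.0)
        decomp = sigma_physio_map(series, 9.0, mask)
        assert decomp.sigma_physio_pct.values[1, 1, 0] == pytest.approx(4.0, abs=1e-9)
        assert decomp.clipped_count == 0

    def test_identity_before_clamping(self):
        """sigma2_physio + sigma2_therm reproduces sigma2_epi exactly."""
        mask = np.ones((3, 3, 1), dtype=bool)
        rng = np.random.default_rng(7)
        data = rng.normal(100, 3, size=(3, 3, 1, 200))
        series = BoldSeries(data=data, tr_seconds=0.25)
        therm = 1.5
        decomp = sigma_physio_map(series, therm, mask)
        expected_epi = data.reshape(-1, 200).var(axis=1, ddof=1)
        assert np.allclose(decomp.sigma2_epi, expected_epi, rtol=1e-12)

    def test_constant_course_zero_percent(self):
        mask = np.ones((2, 2, 1), dtype=bool)
        series = BoldSeries(data=np.full((2, 2, 1, 64), 50.0), tr_seconds=0.25)
        decomp = sigma_physio_map(series, 0.0, mask)
        assert np.allclose(decomp.sigma_physio_pct.values[mask], 0.0)

    def test_thermal_exceeding_total_clamps_and_counts(self):
        mask = np.ones((2, 2, 1), dtype=bool)
        series = self._series_with_exact_variance(mask, 4.0, 100.0)
        decomp = sigma_physio_map(series, 9.0, mask)
        assert np.allclose(decomp.sigma_physio_pct.values[mask], 0.0)
        assert decomp.clipped_count == 4

    def test_nonpositive_mean_marked_undefined(self, rng):
        mask = np.ones((2, 2, 1), dtype=bool)
        data = rng.normal(0.0, 1.0, size=(2, 2, 1, 100))
        data[0, 0, 0, :] += 100.0  # only this voxel has a positive mean
        data[0, 1, 0, :] -= 100.0
        data[1, 0, 0, :] -= 100.0
        data[1, 1, 0, :] -= 100.0
        series = BoldSeries(data=data, tr_seconds=0.25)
        decomp = sigma_physio_map(series, 0.0, mask)
        assert decomp.undefined_count == 3
        assert np.isfinite(decomp.sigma_physio_pct.values[0, 0, 0])


class TestCardiacFrequency:
    def test_sixty_bpm_is_one_hz(self, constant_pulse):
        fc = cardiac_frequency(constant_pulse, tr_seconds=0.25)
        assert fc.f_c_hz == pytest.approx(1.0)

    def test_mean_of_55_and_65(self):
        trace = PulseTrace(times_seconds=np.array([0.0, 1.0]),
                           bpm=np.array([55.0, 65.0]))
        fc = cardiac_frequency(trace, tr_seconds=0.25)
        assert fc.f_c_hz == pytest.approx(1.0)

    def test_nyquist_margin_enforced_in_cs_mode(self):
        trace = PulseTrace(times_seconds=np.arange(3.0),
                           bpm=np.full(3, 150.0))  # 2.5 Hz > Nyquist 2 Hz
        with pytest.raises(ValidationError, match="wb"):
            cardiac_frequency(trace, tr_seconds=0.25, mode="cs")

    def test_window_fallback_when_no_samples_inside(self, caplog):
        trace = PulseTrace(times_seconds=np.array([100.0, 101.0]),
                           bpm=np.array([60.0, 60.0]))
        fc = cardiac_frequency(trace, tr_seconds=0.25, scan_window=(0.0, 10.0))
        assert fc.f_c_hz == pytest.approx(1.0)
        assert "whole trace" in caplog.text

    def test_median_source(self):
        trace = PulseTrace(times_seconds=np.arange(3.0),
                           bpm=np.array([60.0, 60.0, 90.0]))
        fc = cardiac_frequency(trace, tr_seconds=0.25, source="trace_median")
        assert fc.f_c_hz == pytest.approx(1.0)


class TestCardiacPulsatility:
    def _sinusoid_series(self, mask, amp, freq, mean=100.0, n=500, tr=0.25):
        t = np.arange(n) * tr
        course = mean + amp * np.sin(2 * np.pi * freq * t)
        data = np.zeros(mask.shape + (n,))
        data[mask] = course
        return BoldSeries(data=data, tr_seconds=tr)

    def test_on_bin_sinusoid_closed_form(self, constant_pulse):
        """Amplitude 2 on mean 100 at 1.0 Hz -> (2 * 0.008)/0.04 = 0.4%."""
        mask = np.zeros((4, 4, 1), dtype=bool)
        mask[2, 2, 0] = True
        series = self._sinusoid_series(mask, amp=2.0, freq=1.0)
        fc = cardiac_frequency(constant_pulse, tr_seconds=0.25)
        m = cardiac_pulsatility_map(series, fc, mask)
        assert m.values[2, 2, 0] == pytest.approx(0.4, rel=1e-9)

    def test_constant_voxel_is_zero(self, constant_pulse):
        mask = np.ones((2, 2, 1), dtype=bool)
        series = BoldSeries(data=np.full((2, 2, 1, 500), 100.0), tr_seconds=0.25)
        fc = cardiac_frequency(constant_pulse, tr_seconds=0.25)
        m = cardiac_pulsatility_map(series, fc, mask)
        assert np.allclose(m.values[mask], 0.0, atol=1e-12)

    def test_energy_outside_window_excluded(self, constant_pulse):
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 0, 0] = True
        series = self._sinusoid_series(mask, amp=2.0, freq=1.5)
        fc = cardiac_frequency(constant_pulse, tr_seconds=0.25)  # window at 1.0
        m = cardiac_pulsatility_map(series, fc, mask)
        # 1.5 Hz falls between bins; only far spectral-leakage tails can
        # reach the 1.0 Hz window, so the value is ~0 on the 0.4% scale.
        assert m.values[0, 0, 0] == pytest.approx(0.0, abs=0.02)
        # An on-bin out-of-window sinusoid contributes exactly nothing.
        on_bin = self._sinusoid_series(mask, amp=2.0, freq=1.504)
        assert cardiac_pulsatility_map(on_bin, fc, mask).values[0, 0, 0] == \
            pytest.approx(0.0, abs=1e-9)

    def test_amplitude_linearity(self, constant_pulse):
        """Doubling the injected amplitude doubles the map value."""
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 0, 0] = True
        fc = cardiac_frequency(constant_pulse, tr_seconds=0.25)
        v1 = cardiac_pulsatility_map(
            self._sinusoid_series(mask, 1.0, 1.0), fc, mask).values[0, 0, 0]
        v2 = cardiac_pulsatility_map(
            self._sinusoid_series(mask, 2.0, 1.0), fc, mask).values[0, 0, 0]
        assert v2 == pytest.approx(2 * v1, rel=1e-9)

    def test_level_shift_rescales_by_mean_ratio(self, constant_pulse):
        """Adding a constant leaves the spectral numerator unchanged."""
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 0, 0] = True
        fc = cardiac_frequency(constant_pulse, tr_seconds=0.25)
        base = self._sinusoid_series(mask, 2.0, 1.0, mean=100.0)
        shifted = BoldSeries(data=base.data + np.where(mask, 100.0, 0.0)[..., None],
                             tr_seconds=0.25)
        v_base = cardiac_pulsatility_map(base, fc, mask).values[0, 0, 0]
        v_shift = cardiac_pulsatility_map(shifted, fc, mask).values[0, 0, 0]
        assert v_shift == pytest.approx(v_base * 100.0 / 200.0, rel=1e-9)

    def test_aliased_window_is_mode_error(self):
        mask = np.ones((2, 2, 1), dtype=bool)
        series = BoldSeries(data=np.full((2, 2, 1, 128), 100.0), tr_seconds=2.0)
        trace = PulseTrace(times_seconds=np.arange(3.0), bpm=np.full(3, 60.0))
        fc = cardiac_frequency(trace, tr_seconds=0.25, mode="cs")  # fine at cs
        with pytest.raises(ValidationError, match="Nyquist"):
            cardiac_pulsatility_map(series, fc, mask)


class TestTissueSummary:
    def _map_with(self, gm_val, wm_val, wmh_val=None):
        from pulsebold.metrics import VoxelMetricMap

        gm = np.zeros((6, 6, 1), dtype=bool)
        wm = np.zeros_like(gm)
        gm[0:2, :, :] = True
        wm[3:6, :, :] = True
        values = np.full((6, 6, 1), np.nan)
        values[gm] = gm_val
        values[wm] = wm_val
        labels = {"GM": gm, "WM": wm}
        if wmh_val is not None:
            wmh = np.zeros_like(gm)
            wmh[3, :, :] = True
            values[wmh] = wmh_val
            labels["WMH"] = wmh
        m = VoxelMetricMap(values=values, metric_name="sigma_physio",
                           tr_seconds=0.25)
        return m, TissueMasks(labels)

    def test_uniform_map(self):
        m, masks = self._map_with(1.0, 1.0)
        out = tissue_summary(m, masks)
        assert out["GM"]["mean"] == pytest.approx(1.0)
        assert out["WM"]["mean"] == pytest.approx(1.0)

    def test_distinct_class_means(self):
        m, masks = self._map_with(2.0, 1.0)
        out = tissue_summary(m, masks)
        assert out["GM"]["mean"] == pytest.approx(2.0)
        assert out["WM"]["mean"] == pytest.approx(1.0)

    def test_nawm_excludes_lesion_voxels(self):
        """Oracle: mask-set arithmetic on a labelled phantom."""
        m, masks = self._map_with(2.0, 1.0, wmh_val=5.0)
        out = tissue_summary(m, masks)
        nawm = masks.nawm()
        expected = m.values[nawm][np.isfinite(m.values[nawm])].mean()
        assert out["NAWM"]["mean"] == pytest.approx(expected)
        assert out["NAWM"]["mean"] == pytest.approx(1.0)   # lesion excluded
        assert out["WM"]["mean"] > out["NAWM"]["mean"]     # lesion included
        assert out["WMH"]["mean"] == pytest.approx(5.0)

    def test_empty_class_reported_missing_not_zero(self):
        m, masks = self._map_with(2.0, 1.0)
        m.values[masks["GM"]] = np.nan
        out = tissue_summary(m, masks)
        assert np.isnan(out["GM"]["mean"])
        assert out["GM"]["n_voxels"] == 0


class TestCumulativeMotion:
    def test_sum_of_per_volume_displacements(self):
        assert cumulative_motion(np.full(500, 0.05)) == pytest.approx(25.0)

    def test_cohort_scale_displacements(self):
        # ~0.046-0.058 mm/volume accumulates to the 23-29 mm cohort range.
        assert 23.0 == pytest.approx(cumulative_motion(np.full(500, 0.046)))
        assert 29.0 == pytest.approx(cumulative_motion(np.full(500, 0.058)))

    def test_empty_and_negative_rejected(self):
        with pytest.raises(ValidationError):
            cumulative_motion([])
        with pytest.raises(ValidationError):
            cumulative_motion([0.1, -0.1])
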