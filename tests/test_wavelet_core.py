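"""Unit tests for wavelet decomposition and subband scheduling."""

import math

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from ecginverse.wavelet_core import (
    Band,
    SubbandPlan,
    SubbandSeries,
    WaveletSpec,
    band_energy_fraction,
    dwt_step,
    extract_band,
    extract_band_stationary,
    normalize_frequency,
    plan_subband,
    reconstruct_band,
    stationary_detail_bank,
    stopband_gain,
)


class TestWaveletSpec:
    def test_default_is_valid_db4(self):
        spec = WaveletSpec()
        assert spec.family_name == "db4"
        assert spec.taps == 8
        assert len(spec.dec_lo) == len(spec.dec_hi)

    def test_from_name(self):
        spec = WaveletSpec.from_name("db6")
        assert spec.vanishing_moments == 6
        assert spec.taps == 12

    def test_invalid_taps_rejected(self):
        with pytest.raises(ValueError, match="violate"):
            WaveletSpec(dec_lo=(1.0, 0.5, 0.25, 0.1), dec_hi=(0.1, -0.25, 0.5, -1.0))

    def test_unequal_tap_lengths_rejected(self):
        wav = pywt.Wavelet("db4")
        with pytest.raises(ValueError, match="equal length"):
            WaveletSpec(dec_lo=tuple(wav.dec_lo), dec_hi=tuple(wav.dec_hi[:-2]))


class TestBand:
    def test_center(self):
        band = Band(10.0, 20.0, fs_hz=200.0)
        assert band.center_hz == 15.0
        assert band.center_normalized == pytest.approx(0.075)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            Band(20.0, 10.0, fs_hz=200.0)

    def test_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            Band(10.0, 150.0, fs_hz=200.0)

    def test_negative_low(self):
        with pytest.raises(ValueError):
            Band(-1.0, 10.0, fs_hz=200.0)


class TestNormalizeFrequency:
    def test_paper_qrs_center(self):
        # 15 Hz centre of 0-200 Hz support maps to 0.075
        assert normalize_frequency(15.0, 0.0, 200.0) == pytest.approx(0.075)

    def test_lower_endpoint(self):
        assert normalize_frequency(3.0, 3.0, 8.0) == 0.0

    def test_upper_endpoint(self):
        assert normalize_frequency(8.0, 3.0, 8.0) == 1.0

    def test_degenerate_band(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_frequency(5.0, 5.0, 5.0)

    def test_outside_band(self):
        with pytest.raises(ValueError, match="outside"):
            normalize_frequency(9.0, 3.0, 8.0)


class TestDwtStep:
    def test_constant_killed_by_vanishing_moments(self):
        _approx, detail = dwt_step(np.full(256, 3.7))
        assert np.max(np.abs(detail)) < 1e-10

    def test_energy_conservation_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1024)
        approx, detail = dwt_step(x)
        total = float(approx @ approx + detail @ detail)
        assert total == pytest.approx(float(x @ x), rel=1e-6)

    def test_high_band_sinusoid_lands_in_detail(self):
        fs = 200.0
        t = np.arange(2048) / fs
        x = np.sin(2 * np.pi * 0.375 * fs * t)
        approx, detail = dwt_step(x)
        frac = float(detail @ detail) / float(approx @ approx + detail @ detail)
        assert frac >= 0.90

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            dwt_step(np.ones(4))

    def test_non_1d_rejected(self):
        with pytest.raises(ValueError, match="one-dimensional"):
            dwt_step(np.ones((16, 2)))

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=16,
            max_size=300,
        )
    )
    def test_energy_conservation_property(self, values):
        # even lengths: the periodized transform pads odd-length inputs
        x = np.asarray(values[: 2 * (len(values) // 2)])
        approx, detail = dwt_step(x)
        total = float(approx @ approx + detail @ detail)
        assert total == pytest.approx(float(x @ x), rel=1e-6, abs=1e-9)


class TestPlanSubband:
    def test_t_band_level4_mapped_044(self):
        plan = plan_subband(Band(3.0, 8.0, fs_hz=200.0))
        assert plan.level == 4
        assert plan.mapped_center == pytest.approx(0.44)
        assert plan.component_per_level == ("approx", "approx", "approx", "detail")

    def test_qrs_band_level3(self):
        plan = plan_subband(Band(10.0, 20.0, fs_hz=200.0))
        assert plan.level == 3
        assert plan.mapped_center == pytest.approx(0.60)

    def test_centered_band_level1(self):
        # c0 = 0.25 is already centred in the first detail band
        plan = plan_subband(Band(40.0, 60.0, fs_hz=200.0))
        assert plan.level == 1
        assert plan.mapped_center == pytest.approx(0.5)
        assert plan.decimation_factor == 2

    def test_scale_consistency(self):
        # doubling fs halves c0 and pushes the plan one level deeper
        for low, high, fs in [(3, 8, 200), (10, 20, 200), (5, 12, 360)]:
            shallow = plan_subband(Band(low, high, fs_hz=fs))
            deep = plan_subband(Band(low, high, fs_hz=2 * fs))
            assert deep.level == shallow.level + 1
            assert deep.mapped_center == pytest.approx(shallow.mapped_center)

    def test_determinism(self):
        a = plan_subband(Band(3.0, 8.0, fs_hz=250.0))
        b = plan_subband(Band(3.0, 8.0, fs_hz=250.0))
        assert a == b

    def test_center_too_high_rejected(self):
        with pytest.raises(ValueError):
            plan_subband(Band(90.0, 100.0, fs_hz=200.0))


class TestSubbandPlanInvariants:
    def test_terminal_must_be_detail(self):
        with pytest.raises(ValueError, match="detail"):
            SubbandPlan(level=2, component_per_level=("approx", "approx"),
                        mapped_center=0.5)

    def test_path_length_must_match_level(self):
        with pytest.raises(ValueError):
            SubbandPlan(level=3, component_per_level=("approx", "detail"),
                        mapped_center=0.5)


class TestExtractBand:
    def test_in_band_sinusoid_concentrates(self):
        fs = 200.0
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * 15.0 * t)
        series = extract_band(x, fs, Band(10.0, 20.0, fs_hz=fs))
        spec = WaveletSpec()
        coeffs = pywt.wavedec(x, spec.to_pywt(), mode=spec.boundary_mode,
                              level=series.level)
        total = sum(float(c @ c) for c in coeffs)
        frac = float(series.coefficients @ series.coefficients) / total
        assert frac >= 0.70

    def test_out_of_band_sinusoid_rejected(self):
        fs = 200.0
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * 50.0 * t)
        plan = plan_subband(Band(10.0, 20.0, fs_hz=fs))
        series = extract_band(x, fs, plan=plan)
        frac = float(series.coefficients @ series.coefficients) / float(x @ x)
        assert frac < 0.10

    def test_zero_signal(self):
        series = extract_band(np.zeros(1000), 200.0, Band(10.0, 20.0, fs_hz=200.0))
        assert np.all(series.coefficients == 0.0)

    def test_too_short_names_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            extract_band(np.ones(20), 200.0, Band(3.0, 8.0, fs_hz=200.0))

    def test_index_to_time_is_affine(self):
        series = extract_band(
            np.random.default_rng(1).standard_normal(1024),
            200.0, Band(10.0, 20.0, fs_hz=200.0),
        )
        t = series.times()
        steps = np.diff(t)
        assert np.allclose(steps, series.step_s)
        assert series.stride == 2 ** series.level


class TestStationaryBank:
    def test_bank_levels_and_lengths(self):
        x = np.random.default_rng(2).standard_normal(1000)
        bank = stationary_detail_bank(x, WaveletSpec(), depth=4)
        assert sorted(bank) == [1, 2, 3, 4]
        assert all(len(v) == len(x) for v in bank.values())

    def test_shift_invariance(self):
        # the full-rate subband commutes with integer shifts (interior samples)
        x = np.zeros(4096)
        x[1000] = 1.0
        s1 = extract_band_stationary(x, 250.0, Band(10.0, 20.0, fs_hz=250.0))
        s2 = extract_band_stationary(
            np.roll(x, 137), 250.0, Band(10.0, 20.0, fs_hz=250.0)
        )
        assert np.allclose(
            np.roll(s1.coefficients, 137)[500:3500], s2.coefficients[500:3500],
            atol=1e-12,
        )

    def test_full_rate_and_stride(self):
        x = np.random.default_rng(3).standard_normal(1000)
        series = extract_band_stationary(x, 250.0, Band(3.0, 8.0, fs_hz=250.0))
        assert series.stride == 1
        assert len(series.coefficients) == len(x)

    def test_shared_bank_matches_fresh_extraction(self):
        x = np.random.default_rng(4).standard_normal(2000)
        spec = WaveletSpec()
        bank = stationary_detail_bank(x, spec, depth=4)
        for band in (Band(10, 20, fs_hz=250.0), Band(3, 8, fs_hz=250.0)):
            shared = extract_band_stationary(x, 250.0, band, spec=spec,
                                             detail_bank=bank)
            fresh = extract_band_stationary(x, 250.0, band, spec=spec)
            assert np.array_equal(shared.coefficients, fresh.coefficients)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            stationary_detail_bank(np.ones(10), WaveletSpec(), depth=4)


class TestReconstructBand:
    def test_band_concentration_improves(self):
        fs = 200.0
        t = np.arange(2000) / fs
        band = Band(10.0, 20.0, fs_hz=fs)
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * 15.0 * t) + 0.5 * rng.standard_normal(len(t))
        rec = reconstruct_band(x, fs, band)
        assert band_energy_fraction(rec, fs, band) > band_energy_fraction(x, fs, band)
        assert len(rec) == len(x)


class TestStopbandGain:
    def test_n4(self):
        assert stopband_gain(4) == pytest.approx(1.7872e-3, rel=1e-4)

    def test_n6(self):
        assert stopband_gain(6) == pytest.approx(8.7249e-6, rel=1e-4)

    def test_accepts_spec(self):
        assert stopband_gain(WaveletSpec()) == stopband_gain(4)

    def test_strictly_decreasing(self):
        values = [stopband_gain(n) for n in range(1, 21)]
        assert all(b < a for a, b in zip(values, values[1:]))
        assert values[-1] < 1e-15  # factorial dominates; limit is 0

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            stopband_gain(0)


class TestBandEnergyFraction:
    def test_in_band_line(self):
        fs = 200.0
        t = np.arange(4000) / fs
        x = np.sin(2 * np.pi * 15.0 * t)
        assert band_energy_fraction(x, fs, Band(10, 20, fs_hz=fs)) >= 0.99

    def test_out_of_band_line(self):
        fs = 200.0
        t = np.arange(4000) / fs
        x = np.sin(2 * np.pi * 15.0 * t)
        assert band_energy_fraction(x, fs, Band(30, 40, fs_hz=fs)) <= 0.01

    def test_qrs_train_mostly_below_40hz(self):
        from ecginverse.synthetic_ecg import SimConfig, generate_beats

        config = SimConfig(t_amplitude=0.0, p_amplitude=0.0, seed=0)
        signal, _ = generate_beats(config)
        assert band_energy_fraction(signal, config.fs, Band(0, 40, fs_hz=config.fs)) >= 0.90

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            band_energy_fraction(np.array([]), 200.0, Band(10, 20, fs_hz=200.0))


class TestSubbandSeries:
    def test_default_stride_is_decimation(self):
        s = SubbandSeries(coefficients=np.zeros(8), level=3, fs_hz=200.0,
                          delay_samples=0.0)
        assert s.stride == 8
        assert s.step_s == pytest.approx(8 / 200.0)

    def test_index_to_time_includes_delay(self):
        s = SubbandSeries(coefficients=np.zeros(8), level=2, fs_hz=100.0,
                          delay_samples=3.0, stride=1)
        assert s.index_to_time(7) == pytest.approx(0.10)
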