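"""Per-epoch gait characteristic estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitrisk as gr
from gaitrisk import features as ft

from .conftest import FS, make_sine
from .oracles import autocorr_lag_search, sampen_bruteforce


class TestRms:
    def test_unit_sine(self):
        assert ft.rms(make_sine(1.0)) == pytest.approx(1 / math.sqrt(2), rel=1e-3)

    def test_constant_is_zero(self):
        assert ft.rms(np.full(100, 3.7)) == 0.0

    def test_matches_definition_on_arbitrary_vector(self):
        x = np.array([0.3, -1.2, 2.2, 0.1, -0.4, 1.9, -2.2, 0.5, 0.0, -1.1])
        xc = x - x.mean()
        assert ft.rms(x) == pytest.approx(math.sqrt(np.sum(xc**2) / len(x)))


class TestStrideRegularity:
    def test_periodic_signal_is_one(self):
        x = make_sine(1.0) + 0.3 * make_sine(3.0)
        assert ft.stride_regularity(x, 100) == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_decorrelates(self):
        x = np.random.default_rng(3).standard_normal(1000)
        assert abs(ft.stride_regularity(x, 100)) < 0.15

    def test_matches_autocovariance_ratio_at_found_lag(self):
        rng = np.random.default_rng(0)
        x = make_sine(1.0, amp=2.0) + 0.5 * rng.standard_normal(1000)
        val = ft.stride_regularity(x, 100)
        # definitional unbiased autocovariance ratio, exhaustive over the
        # same +/-10% lag window
        xc = x - x.mean()
        n = len(xc)
        denom = (xc @ xc) / n
        direct = max(
            (xc[: n - k] @ xc[k:]) / (n - k) / denom for k in range(90, 111)
        )
        assert val == pytest.approx(direct, abs=1e-12)


class TestLowFrequencyPercentage:
    def test_sine_above_cutoff(self):
        assert ft.low_frequency_percentage(make_sine(2.0), FS, 0.7) < 1.0

    def test_sine_below_cutoff(self):
        assert ft.low_frequency_percentage(make_sine(0.5), FS, 0.7) > 99.0

    def test_equal_mixture_splits_power(self):
        x = make_sine(0.5) + make_sine(2.0)
        assert ft.low_frequency_percentage(x, FS, 0.7) == pytest.approx(50.0, abs=2.0)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(Exception):
            ft.low_frequency_percentage(make_sine(2.0), FS, 60.0)


class TestIndexOfHarmonicity:
    def test_pure_fundamental(self):
        assert ft.index_of_harmonicity(make_sine(2.0), FS, 2.0) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_equal_fundamental_and_harmonic(self):
        x = make_sine(2.0) + make_sine(4.0)
        assert ft.index_of_harmonicity(x, FS, 2.0) == pytest.approx(0.5, abs=0.01)

    def test_three_harmonic_power_ratio(self):
        x = make_sine(2.0) + 0.5 * make_sine(4.0) + 0.25 * make_sine(6.0)
        expected = 1.0 / (1.0 + 0.25 + 0.0625)
        assert ft.index_of_harmonicity(x, FS, 2.0) == pytest.approx(expected, abs=0.01)


class TestHarmonicRatio:
    def test_even_to_odd_amplitude_ratio(self):
        x = 1.0 * make_sine(2.0) + 0.5 * make_sine(1.0)
        hr, capped = ft.harmonic_ratio(x, FS, 1.0, "vt")
        assert not capped
        assert hr == pytest.approx(2.0, rel=0.02)

    def test_ml_convention_inverts(self):
        x = 1.0 * make_sine(2.0) + 0.5 * make_sine(1.0)
        hr, _ = ft.harmonic_ratio(x, FS, 1.0, "ml")
        assert hr == pytest.approx(0.5, rel=0.02)

    def test_even_only_capped_and_flagged(self):
        hr, capped = ft.harmonic_ratio(make_sine(2.0), FS, 1.0, "vt")
        assert capped
        assert hr == ft.FeatureConfig().hr_cap

    def test_decreases_with_asymmetry(self):
        values = []
        for asym in (0.1, 0.3, 0.5, 0.7, 0.9):
            p = gr.GaitSignalParams(asymmetry=asym, noise_sd=0.0, freq_jitter_sd=0.0)
            ep = gr.synth_gait_epoch(p, seed=0)
            hr, _ = ft.harmonic_ratio(ep.vt - ep.vt.mean(), FS, 1.0, "vt")
            values.append(hr)
        assert all(a > b for a, b in zip(values, values[1:]))


class TestFrequencyVariability:
    def test_constant_frequency_near_zero(self):
        assert ft.frequency_variability(make_sine(2.0), FS, (0.8, 3.2)) < 0.01

    def test_larger_jitter_larger_value(self):
        vals = {}
        for jit in (0.01, 0.05):
            p = gr.GaitSignalParams(freq_jitter_sd=jit, noise_sd=0.0)
            ep = gr.synth_gait_epoch(p, seed=12)
            vals[jit] = ft.frequency_variability(
                ep.vt - ep.vt.mean(), FS, (0.8, 3.2)
            )
        assert vals[0.05] > vals[0.01]

    def test_amplitude_scale_invariant(self):
        x = make_sine(1.8) + 0.2 * make_sine(3.6)
        a = ft.frequency_variability(x, FS, (0.8, 3.2))
        b = ft.frequency_variability(5.0 * x, FS, (0.8, 3.2))
        assert a == pytest.approx(b, abs=1e-12)


class TestLocalDynamicStability:
    def test_closed_orbit_does_not_diverge(self):
        rng = np.random.default_rng(5)
        sine = ft.local_dynamic_stability(make_sine(1.0), FS, 100)
        noise = ft.local_dynamic_stability(rng.standard_normal(1000), FS, 100)
        assert abs(sine) < 0.05 * abs(noise)

    def test_noise_increases_divergence(self):
        rng = np.random.default_rng(8)
        clean = make_sine(1.0)
        noisy = clean + 0.3 * rng.standard_normal(1000)
        assert ft.local_dynamic_stability(noisy, FS, 100) > ft.local_dynamic_stability(
            clean, FS, 100
        )

    def test_deterministic(self):
        x = make_sine(1.0) + 0.1 * np.random.default_rng(2).standard_normal(1000)
        a = ft.local_dynamic_stability(x, FS, 100)
        b = ft.local_dynamic_stability(x, FS, 100)
        assert a == b

    def test_short_signal_undefined(self):
        assert math.isnan(ft.local_dynamic_stability(make_sine(1.0, n=300), FS, 100))


class TestSampleEntropy:
    def test_constant_signal_zero(self):
        assert ft.sample_entropy(np.full(50, 2.0)) == 0.0

    def test_matches_bruteforce_exactly_on_short_vector(self):
        x = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1], dtype=float)
        p = ft.SampEnParams(m=2, r=0.2)
        assert ft.sample_entropy(x, p) == sampen_bruteforce(x, 2, 0.2)

    def test_noise_exceeds_sinusoid(self):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(1000)
        sine = make_sine(1.0, amp=noise.std() * math.sqrt(2))
        assert ft.sample_entropy(noise) > ft.sample_entropy(sine)

    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 20.0))
    def test_scale_invariance(self, seed, scale):
        x = np.random.default_rng(seed).standard_normal(120)
        a = ft.sample_entropy(x, ft.SampEnParams(m=2, r=0.3))
        b = ft.sample_entropy(scale * x, ft.SampEnParams(m=2, r=0.3))
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, rel=1e-9)


class TestDominantFrequencyAmplitude:
    def test_pure_sine_amplitude(self):
        v = ft.dominant_frequency_amplitude(make_sine(2.0, amp=2.0), FS, 2.0)
        assert v == pytest.approx(2.0, rel=0.02)

    def test_linearity(self):
        a = ft.dominant_frequency_amplitude(make_sine(2.1, amp=2.0), FS, 2.0)
        b = ft.dominant_frequency_amplitude(make_sine(2.1, amp=1.0), FS, 2.0)
        assert a == pytest.approx(2.0 * b, rel=1e-9)

    def test_matches_periodogram_integration(self):
        ep = gr.synth_gait_epoch(
            gr.GaitSignalParams(noise_sd=0.0, freq_jitter_sd=0.0), seed=0
        )
        x = ep.vt - ep.vt.mean()
        v = ft.dominant_frequency_amplitude(x, FS, 2.0)
        # direct Hann periodogram energy integration around the 2 Hz peak
        n = len(x)
        w = np.hanning(n)
        spec = np.abs(np.fft.rfft(w * x)) ** 2
        freqs = np.fft.rfftfreq(n, 1 / FS)
        pk = np.argmax(np.where((freqs > 1.4) & (freqs < 2.6), spec, 0))
        e = spec[pk - 3 : pk + 4].sum()
        expected = 2.0 * math.sqrt(e / (n * np.sum(w * w)))
        assert v == pytest.approx(expected, rel=1e-9)


class TestStrideFrequency:
    def test_noiseless_exact(self):
        ep = gr.synth_gait_epoch(
            gr.GaitSignalParams(noise_sd=0.0, freq_jitter_sd=0.0), seed=0
        )
        assert ft.stride_frequency(ep) == pytest.approx(1.0, abs=0.01)

    def test_white_noise_flagged(self):
        rng = np.random.default_rng(17)
        ep = gr.AccelEpoch(
            vt=rng.standard_normal(1000),
            ml=rng.standard_normal(1000),
            ap=rng.standard_normal(1000),
        )
        assert math.isnan(ft.stride_frequency(ep))

    def test_jittered_stride_matches_lag_search_oracle(self):
        p = gr.GaitSignalParams(stride_frequency=0.9, freq_jitter_sd=0.02)
        ep = gr.synth_gait_epoch(p, seed=5)
        est = ft.stride_frequency(ep)
        assert est == pytest.approx(0.9, abs=0.05)
        oracle = autocorr_lag_search(ep.vt, FS, (0.4, 1.6))
        assert est == pytest.approx(oracle, abs=0.05)

    def test_asymmetric_slow_gait_not_halved(self):
        # stride-fundamental-dominant spectrum must not halve the estimate
        from gaitrisk.synth import _quality_to_signal_params

        p, _ = _quality_to_signal_params(-1.9, gr.GaitSignalParams())
        ep = gr.synth_gait_epoch(p, seed=7)
        assert ft.stride_frequency(ep) == pytest.approx(p.stride_frequency, abs=0.08)


class TestGaitSpeed:
    def test_known_excursion_closed_form(self):
        amp = gr.vt_amplitude_for_excursion(0.02, 1.0)
        p = gr.GaitSignalParams(
            noise_sd=0.0, freq_jitter_sd=0.0, asymmetry=0.0,
            harmonic_amplitudes_even={"vt": (amp, 0, 0, 0), "ml": (0, 0, 0, 0),
                                      "ap": (1.0, 0, 0, 0)},
        )
        ep = gr.synth_gait_epoch(p, seed=0)
        speed, var = ft.gait_speed_and_variability(ep, 1.0)
        expected = 2.0 * 2.0 * math.sqrt(2 * 0.9 * 0.02 - 0.02**2)
        assert speed == pytest.approx(expected, rel=0.05)
        assert var == pytest.approx(0.0, abs=1e-6)

    def test_zero_excursion_zero_speed(self):
        z = gr.AccelEpoch(vt=np.zeros(1000), ml=np.zeros(1000), ap=np.zeros(1000))
        speed, var = ft.gait_speed_and_variability(z, 1.0)
        assert speed == 0.0


class TestExtractFeatures:
    def test_clean_epoch_fully_defined(self, clean_epoch):
        values, reasons = gr.extract_features(clean_epoch)
        defined = {k: v for k, v in values.items() if np.isfinite(v)}
        assert set(gr.FEATURE_NAMES) <= set(defined)
        assert values["stride_regularity_vt"] > 0.99
        assert values["index_of_harmonicity_vt"] > 0.99
        assert values["stride_time"] == pytest.approx(
            1.0 / values["stride_frequency"]
        )

    def test_all_zero_signal_only_rms_defined(self):
        z = gr.AccelEpoch(vt=np.zeros(1000), ml=np.zeros(1000), ap=np.zeros(1000))
        values, reasons = gr.extract_features(z)
        assert values["rms_vt"] == 0.0
        undefined = [k for k in gr.FEATURE_NAMES if not np.isfinite(values[k])]
        assert set(undefined) == set(gr.FEATURE_NAMES) - {"rms_vt", "rms_ml", "rms_ap"}

    def test_pure_function_of_epoch(self, default_epoch):
        v1, _ = gr.extract_features(default_epoch)
        v2, _ = gr.extract_features(default_epoch)
        assert v1 == v2

    @settings(max_examples=4)
    @given(st.floats(0.5, 8.0))
    def test_scale_invariant_features(self, c):
        ep = gr.synth_gait_epoch(gr.GaitSignalParams(), seed=21)
        scaled = gr.AccelEpoch(vt=c * ep.vt, ml=c * ep.ml, ap=c * ep.ap)
        v1, _ = gr.extract_features(ep)
        v2, _ = gr.extract_features(scaled)
        for base in ("stride_regularity", "index_of_harmonicity", "harmonic_ratio",
                     "frequency_variability", "sample_entropy",
                     "low_frequency_percentage"):
            for ax in gr.AXES:
                assert v2[f"{base}_{ax}"] == pytest.approx(
                    v1[f"{base}_{ax}"], rel=1e-6, abs=1e-9
                )
        for ax in gr.AXES:
            assert v2[f"rms_{ax}"] == pytest.approx(c * v1[f"rms_{ax}"], rel=1e-9)
            assert v2[f"dominant_frequency_amplitude_{ax}"] == pytest.approx(
                c * v1[f"dominant_frequency_amplitude_{ax}"], rel=1e-6
            )

    def test_rejects_out_of_range_epoch(self):
        bad = gr.AccelEpoch(vt=np.full(1000, 80.0), ml=np.zeros(1000),
                            ap=np.zeros(1000))
        with pytest.raises(Exception):
            gr.extract_features(bad)
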