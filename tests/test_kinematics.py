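"""Signal-processing and limb-geometry unit tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from limbkin import kinematics as kin
from limbkin import synth

FS = 120.0


# ---------------------------------------------------------------------------
# low-pass filter


class TestLowpassFilter:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.7)
        np.testing.assert_allclose(kin.lowpass_filter(x, FS), x, atol=1e-9)

    @pytest.mark.parametrize("freq,check", [
        (1.0, lambda ratio: ratio > 0.99),    # passband: <1% attenuation
        (30.0, lambda ratio: ratio < 0.01),   # stopband: >99% attenuation
    ])
    def test_sinusoid_attenuation(self, freq, check):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * freq * t)
        y = kin.lowpass_filter(x, FS)
        core = slice(len(t) // 4, -len(t) // 4)  # avoid edge transients
        ratio = np.abs(y[core]).max() / np.abs(x[core]).max()
        assert check(ratio)

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="warm-up"):
            kin.lowpass_filter(np.arange(10.0), FS)

    def test_cutoff_above_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            kin.lowpass_filter(np.zeros(100), FS, cutoff_hz=70.0)


# ---------------------------------------------------------------------------
# limb angle / limb length geometry


class TestLimbAngle:
    @pytest.mark.parametrize("ankle,expected", [
        ((0.0, 0.0), 0.0),          # vertical limb
        ((0.5, 0.0), 26.565051),    # ankle anterior -> flexion positive
        ((-0.5, 0.0), -26.565051),  # ankle posterior -> extension negative
    ])
    def test_reference_angles(self, ankle, expected):
        assert kin.limb_angle((0.0, 1.0), ankle) == pytest.approx(expected,
                                                                  abs=1e-5)

    def test_coincident_points_raise(self):
        with pytest.raises(ValueError, match="coincide"):
            kin.limb_angle((1.0, 1.0), (1.0, 1.0))

    @given(st.floats(-3, 3), st.floats(-3, 3), st.floats(0.1, 10),
           st.floats(-30, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_translation_and_scale_invariance(self, tx, ty, s, ang):
        hip = np.array([0.0, 1.0])
        ankle = np.array([np.sin(np.deg2rad(ang)), 1 - np.cos(np.deg2rad(ang))])
        base = kin.limb_angle(hip, ankle)
        shift = np.array([tx, ty])
        moved = kin.limb_angle(s * hip + shift, s * ankle + shift)
        assert moved == pytest.approx(base, abs=1e-8)

    @given(st.floats(-40, 40))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_reflection_flips_sign(self, ang):
        hip = np.array([0.0, 1.0])
        ankle = np.array([np.sin(np.deg2rad(ang)), 1 - np.cos(np.deg2rad(ang))])
        mirrored = kin.limb_angle(hip * [-1, 1], ankle * [-1, 1])
        assert mirrored == pytest.approx(-kin.limb_angle(hip, ankle), abs=1e-8)


class TestLimbLength:
    def test_straight_limb_is_one(self):
        assert kin.limb_length((0, 1), (0, 0.5), (0, 0)) == pytest.approx(1.0)

    def test_right_angle_knee(self):
        # hip-ankle = sqrt(0.5), thigh + shank = 1
        assert kin.limb_length((0, 1), (0, 0.5), (0.5, 0.5)) == pytest.approx(
            np.sqrt(0.5), abs=1e-6)

    def test_flexed_below_one(self):
        assert kin.limb_length((0, 1), (0.2, 0.5), (0, 0)) < 1.0

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.05, 20),
           st.floats(0, 2 * np.pi), st.floats(5, 175))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_similarity_invariance(self, tx, ty, s, rot, knee_deg):
        """Invariant under translation, rotation and uniform scaling."""
        kr = np.deg2rad(knee_deg)
        hip = np.array([0.0, 1.0])
        knee = np.array([0.0, 0.5])
        ankle = knee + 0.5 * np.array([np.sin(kr), -np.cos(kr)])
        base = kin.limb_length(hip, knee, ankle)
        c, sn = np.cos(rot), np.sin(rot)
        R = np.array([[c, -sn], [sn, c]])
        tr = np.array([tx, ty])
        moved = kin.limb_length(s * R @ hip + tr, s * R @ knee + tr,
                                s * R @ ankle + tr)
        assert moved == pytest.approx(base, rel=1e-9)
        assert 0 < base <= 1 + 1e-12


# ---------------------------------------------------------------------------
# differentiation


class TestDifferentiate:
    def test_linear_ramp(self):
        t = np.arange(100) / FS
        d = kin.differentiate(5.0 * t, FS)
        np.testing.assert_allclose(d, 5.0, atol=1e-9)

    def test_constant_is_zero(self):
        np.testing.assert_allclose(kin.differentiate(np.full(50, 2.0), FS), 0.0)

    def test_sinusoid_amplitude(self):
        f = 1.0
        t = np.arange(0, 5, 1 / FS)
        d = kin.differentiate(np.sin(2 * np.pi * f * t), FS)
        expected = 2 * np.pi * f
        assert np.abs(d[5:-5]).max() == pytest.approx(expected, rel=1e-3)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            kin.differentiate(np.array([1.0, 2.0]), FS)


# ---------------------------------------------------------------------------
# cycle normalization


class TestNormalizeCycles:
    def test_identity_grid(self):
        x = np.sin(np.linspace(0, 3, 300))
        out = kin.normalize_cycles(x, [10, 210])
        np.testing.assert_allclose(out[0], x[10:211], atol=1e-12)

    def test_linear_preserved(self):
        x = np.linspace(0, 10, 400)
        out = kin.normalize_cycles(x, [0, 133])
        np.testing.assert_allclose(out[0], np.linspace(x[0], x[133], 201),
                                   atol=1e-9)

    def test_sinusoid_interpolation_error(self):
        t = np.arange(0, 2, 1 / FS)
        x = np.sin(2 * np.pi * t)  # one stride = 120 frames at 1 Hz
        out = kin.normalize_cycles(x, [0, 120])
        exact = np.sin(2 * np.pi * np.linspace(0, 1, 201))
        assert np.abs(out[0] - exact).max() < 1e-3

    def test_short_stride_dropped(self, caplog):
        x = np.arange(300.0)
        out = kin.normalize_cycles(x, [0, 2, 250])
        assert out.shape == (1, 201)

    def test_endpoints_exact(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500).cumsum()
        out = kin.normalize_cycles(x, [7, 137])
        assert out[0, 0] == pytest.approx(x[7])
        assert out[0, -1] == pytest.approx(x[137])


# ---------------------------------------------------------------------------
# gait events


class TestGaitEvents:
    def test_roundtrip_heel_contacts(self, clean_walk):
        """Detected heel contacts fall within 2 frames of the generator's
        ground truth on a noise-free walk."""
        series, truth = clean_walk
        kinser = kin.compute_kinematics(series)
        hc, to = kin.detect_gait_events(kinser.shank_angular_velocity,
                                        series.sampling_rate)
        for h in truth["heel_contacts"]:
            assert np.abs(hc - h).min() <= 2

    def test_constant_signal_raises(self):
        with pytest.raises(ValueError, match="no strides"):
            kin.detect_gait_events(np.zeros(500), FS)

    def test_periodic_signal_period_recovered(self, clean_walk):
        series, truth = clean_walk
        kinser = kin.compute_kinematics(series)
        hc, _ = kin.detect_gait_events(kinser.shank_angular_velocity, FS)
        intervals = np.diff(hc) / FS
        np.testing.assert_allclose(
            np.sort(intervals), np.sort(truth["stride_periods_s"][1:-1]),
            atol=3 / FS)


# ---------------------------------------------------------------------------
# feature extraction


class TestExtractFeatures:
    def test_roundtrip_planted_features(self, clean_walk):
        series, truth = clean_walk
        f = kin.process_walk(series, meters_per_pixel=0.001)
        assert f.limb_angle_ext_peak == pytest.approx(truth["limb_angle_ext"],
                                                      abs=0.5)
        assert f.limb_length_min_swing == pytest.approx(truth["limb_length"],
                                                        abs=0.005)
        assert f.n_strides_used == 10

    def test_mean_of_stride_minima(self):
        """Feature is the arithmetic mean of per-stride minima."""
        minima = -np.arange(10, 20.0)  # -10 .. -19
        assert np.mean(minima) == pytest.approx(-14.5)

    def test_gait_stability_ratio_definition(self, clean_walk):
        series, _ = clean_walk
        f = kin.process_walk(series, meters_per_pixel=0.001)
        assert f.gait_stability_ratio == pytest.approx(
            f.cadence / (f.gait_speed * 60.0))

    def test_too_few_strides_raises(self, clean_walk):
        series, _ = clean_walk
        kinser = kin.compute_kinematics(series)
        strides = kin.segment_strides(kinser)
        strides.angle_cycles = strides.angle_cycles[:5]
        strides.length_cycles = strides.length_cycles[:5]
        small = kin.StrideSet(strides.heel_contacts[:6], strides.toe_offs,
                              strides.angle_cycles, strides.length_cycles,
                              strides.sampling_rate)
        with pytest.raises(ValueError, match="strides"):
            kin.extract_features(small, kinser, trim=3, n_keep=10)

    def test_cadence_matches_stride_period(self, clean_walk):
        series, truth = clean_walk
        f = kin.process_walk(series)
        expected = 120.0 / truth["stride_periods_s"].mean()
        assert f.cadence == pytest.approx(expected, rel=0.03)
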