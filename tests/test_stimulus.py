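"""Tests for the noisy dot-field stimulus, display geometry and bar noise."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram

from svvkit.stimulus import (
    AnnulusSpec,
    BarNoiseSpec,
    NoiseSpec,
    advance_frame,
    generate_bar_noise,
    mean_field_velocity,
    n_dots,
    sample_dot_field,
    scale_constant,
    visual_angle,
)


class TestScaleConstant:
    def test_no_noise_no_rescaling(self):
        assert scale_constant(0.0) == 1.0

    def test_half_noise_closed_form(self):
        assert scale_constant(0.5) == pytest.approx(math.pi / 2, abs=1e-12)

    def test_monte_carlo_mean_cosine_oracle(self, rng):
        # 1/c(p) must equal the mean cosine of the jump rotation
        for p in (0.25, 0.5, 0.8):
            draws = rng.uniform(-math.pi * p, math.pi * p, 4_000_000)
            assert 1.0 / scale_constant(p) == pytest.approx(np.cos(draws).mean(), abs=1e-3)

    def test_divergence_near_full_noise(self):
        assert scale_constant(0.998) > 100.0
        for bad in (1.0, 1.2, -0.1):
            with pytest.raises(ValueError):
                scale_constant(bad)

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_and_at_least_one(self, p):
        assert scale_constant(p) >= 1.0
        assert scale_constant(min(p + 0.005, 0.995)) >= scale_constant(p)


class TestGeometry:
    def test_printed_visual_angles(self):
        assert round(visual_angle(0.48, 0.60)) == 44
        assert round(visual_angle(2.44, 0.60)) == 128

    def test_degenerate_and_invalid(self):
        assert visual_angle(0.0, 0.6) == 0.0
        with pytest.raises(ValueError):
            visual_angle(1.0, 0.0)

    def test_dot_count_from_density(self):
        assert n_dots(AnnulusSpec()) == 6563
        assert n_dots(AnnulusSpec(dot_density=0.0)) == 0
        assert n_dots(AnnulusSpec(inner_diameter=1.0, outer_diameter=1.0)) == 0


class TestDotField:
    def test_zero_noise_is_rigid_rotation(self, rng):
        ann = AnnulusSpec()
        spec = NoiseSpec(noise_fraction=0.0, field_velocity=16.0, frame_rate=60.0)
        field = sample_dot_field(ann, rng, n=500)
        new = advance_frame(field, ann, spec, rng)
        expected = math.radians(16.0) / 60.0
        keep = ~new.respawned
        np.testing.assert_allclose(new.last_jump_azimuth[keep], expected, rtol=1e-3)

    def test_mean_velocity_preserved_under_heavy_noise(self, rng):
        ann = AnnulusSpec()
        spec = NoiseSpec(noise_fraction=0.8, field_velocity=16.0, frame_rate=60.0)
        mean, se = mean_field_velocity(ann, spec, n_frames=3, rng=rng)
        assert mean == pytest.approx(16.0, abs=3 * se)

    def test_jump_magnitude_inflated_by_scale_constant(self, rng):
        # at 80% noise each jump is ~4.3x the rigid jump even though the mean
        # field velocity is unchanged
        ann = AnnulusSpec()
        spec = NoiseSpec(noise_fraction=0.8, field_velocity=16.0, frame_rate=60.0)
        field = sample_dot_field(ann, rng, n=2000)
        x0 = field.radius * np.cos(field.azimuth)
        y0 = field.radius * np.sin(field.azimuth)
        new = advance_frame(field, ann, spec, rng)
        keep = ~new.respawned
        d = np.hypot(
            new.radius[keep] * np.cos(new.azimuth[keep]) - x0[keep],
            new.radius[keep] * np.sin(new.azimuth[keep]) - y0[keep],
        )
        rigid = field.radius[keep] * math.radians(16.0) / 60.0
        assert np.mean(d / rigid) == pytest.approx(scale_constant(0.8), rel=0.01)
        assert scale_constant(0.8) == pytest.approx(4.2757, abs=1e-3)

    def test_full_noise_without_rescaling_has_no_net_motion(self, rng):
        ann = AnnulusSpec()
        spec = NoiseSpec(noise_fraction=0.8, field_velocity=16.0, frame_rate=60.0)
        mean, se = mean_field_velocity(
            ann, spec, n_frames=10, rng=rng, rescale=False, noise_fraction=1.0
        )
        assert abs(mean) < 3 * se

    def test_dots_never_leave_annulus(self, rng):
        ann = AnnulusSpec()
        spec = NoiseSpec(noise_fraction=0.8, field_velocity=16.0, frame_rate=60.0)
        field = sample_dot_field(ann, rng, n=1000)
        for _ in range(50):
            field = advance_frame(field, ann, spec, rng)
            assert np.all(field.radius >= ann.inner_radius - 1e-12)
            assert np.all(field.radius <= ann.outer_radius + 1e-12)


class TestBarNoise:
    def test_pooled_sd_and_range(self):
        rng = np.random.default_rng(11)
        spec = BarNoiseSpec()
        traces = [generate_bar_noise(spec, 50.0, rng) for _ in range(300)]
        pooled = np.concatenate(traces)
        assert pooled.std() == pytest.approx(9.6, rel=0.02)
        assert np.abs(pooled).max() <= 35.9

    def test_band_limited(self):
        rng = np.random.default_rng(12)
        spec = BarNoiseSpec()
        power = []
        for _ in range(100):
            f, p = periodogram(generate_bar_noise(spec, 50.0, rng), fs=30.0, window="hann")
            power.append(p)
        power = np.mean(power, axis=0)
        assert power[f > 0.25].sum() / power.sum() < 0.01

    def test_bitwise_reproducible(self):
        spec = BarNoiseSpec()
        a = generate_bar_noise(spec, 50.0, np.random.default_rng(99))
        b = generate_bar_noise(spec, 50.0, np.random.default_rng(99))
        assert np.array_equal(a, b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_bar_noise(BarNoiseSpec(), 0.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            BarNoiseSpec(target_sd=-1.0)
        with pytest.raises(ValueError):
            BarNoiseSpec(range_limit=5.0)
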