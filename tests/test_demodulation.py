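"""Three-phase synthesis/demodulation and flat-field correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfdikit.demodulation import (
    EXPERIMENT1_FREQUENCIES,
    EXPERIMENT2_FREQUENCIES,
    THREE_PHASE_OFFSETS,
    DemodulatedPair,
    PatternImageSet,
    demodulate,
    flat_field_correct,
    load_pattern_set,
    save_pattern_set,
    synthesize_patterns,
)


def _random_fields(rng, shape=(8, 16)):
    dc = rng.uniform(0.2, 0.8, shape)
    ac = dc * rng.uniform(0.0, 1.0, shape)
    return dc, ac


class TestSynthesize:
    def test_zero_ac_gives_three_identical_constants(self):
        dc = np.full((4, 6), 0.7)
        ps = synthesize_patterns(dc, np.zeros_like(dc), fx=0.1, pixel_pitch=0.5)
        for img in ps.images:
            np.testing.assert_allclose(img, 0.7)

    def test_zero_frequency_pattern_values(self):
        """At fx = 0 the first phase image is dc - ac/2 (cos(-2pi/3) = -1/2)."""
        dc = np.full((3, 5), 0.6)
        ac = np.full((3, 5), 0.25)
        ps = synthesize_patterns(dc, ac, fx=0.0, pixel_pitch=0.2)
        np.testing.assert_allclose(ps.images[0], 0.6 - 0.125, rtol=1e-12)
        np.testing.assert_allclose(ps.images[1], 0.85, rtol=1e-12)
        np.testing.assert_allclose(ps.images[2], 0.6 - 0.125, rtol=1e-12)

    def test_ac_exceeding_dc_rejected(self):
        dc = np.full((2, 2), 0.3)
        ac = np.full((2, 2), 0.4)
        with pytest.raises(ValueError, match="negative intensity"):
            synthesize_patterns(dc, ac, fx=0.1, pixel_pitch=0.2)

    def test_wrong_phase_order_rejected(self):
        imgs = np.ones((3, 2, 2))
        bad = (0.0, -2 * math.pi / 3, 2 * math.pi / 3)
        with pytest.raises(ValueError, match="phase offsets"):
            PatternImageSet(imgs, fx=0.1, pixel_pitch=0.2, phase_offsets=bad)


class TestDemodulate:
    def test_constant_pixel_triplet(self):
        imgs = np.full((3, 2, 2), 5.0)
        pair = demodulate(PatternImageSet(imgs, fx=0.0, pixel_pitch=0.1))
        np.testing.assert_allclose(pair.dc, 5.0)
        np.testing.assert_allclose(pair.ac, 0.0)

    def test_reference_triplet_1_2_3(self):
        imgs = np.stack([np.full((1, 1), v) for v in (1.0, 2.0, 3.0)])
        pair = demodulate(PatternImageSet(imgs, fx=0.0, pixel_pitch=0.1))
        assert pair.dc[0, 0] == pytest.approx(2.0, rel=1e-15)
        assert pair.ac[0, 0] == pytest.approx(1.1547005383792515, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        fx=st.floats(0.0, 0.3),
        pitch=st.floats(0.05, 0.5),
    )
    def test_round_trip_is_identity(self, seed, fx, pitch):
        rng = np.random.default_rng(seed)
        dc, ac = _random_fields(rng)
        pair = demodulate(synthesize_patterns(dc, ac, fx=fx, pixel_pitch=pitch))
        np.testing.assert_allclose(pair.dc, dc, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(pair.ac, ac, rtol=1e-12, atol=1e-12)

    def test_global_phase_leaves_dc_and_ac_unchanged(self, rng):
        """The demodulation is insensitive to a common phase offset."""
        dc, ac = _random_fields(rng)
        cols = np.arange(dc.shape[1]) * 0.2
        for phase0 in rng.uniform(0, 2 * math.pi, 5):
            imgs = np.stack(
                [
                    dc + ac * np.cos(2 * math.pi * 0.1 * cols + phi + phase0)
                    for phi in THREE_PHASE_OFFSETS
                ]
            )
            np.clip(imgs, 0.0, None, out=imgs)
            pair = demodulate(PatternImageSet(imgs, fx=0.1, pixel_pitch=0.2))
            np.testing.assert_allclose(pair.dc, dc, rtol=1e-10)
            np.testing.assert_allclose(pair.ac, ac, rtol=1e-9, atol=1e-12)

    def test_scaling_commutes(self, rng):
        dc, ac = _random_fields(rng)
        ps = synthesize_patterns(dc, ac, fx=0.07, pixel_pitch=0.3)
        scaled = PatternImageSet(3.5 * ps.images, fx=0.07, pixel_pitch=0.3)
        pair = demodulate(ps)
        pair_scaled = demodulate(scaled)
        np.testing.assert_allclose(pair_scaled.dc, 3.5 * pair.dc, rtol=1e-12)
        np.testing.assert_allclose(pair_scaled.ac, 3.5 * pair.ac, rtol=1e-12)

    def test_ac_zero_wherever_ac_field_zero(self, rng):
        dc = rng.uniform(0.2, 0.9, (6, 12))
        ac = np.zeros_like(dc)
        ac[:, 6:] = dc[:, 6:] * 0.5
        pair = demodulate(synthesize_patterns(dc, ac, fx=0.12, pixel_pitch=0.25))
        np.testing.assert_allclose(pair.ac[:, :6], 0.0, atol=1e-13)
        assert np.all(pair.ac[:, 6:] > 1e-6)


class TestFlatField:
    def test_self_correction_yields_reference_reflectance(self, rng):
        raster = rng.uniform(0.5, 1.5, (5, 7))
        pair = DemodulatedPair(dc=raster, ac=raster * 0.5, fx=0.1)
        out = flat_field_correct(pair, pair, reference_reflectance=0.99)
        np.testing.assert_allclose(out.dc, 0.99, rtol=1e-12)
        np.testing.assert_allclose(out.ac, 0.99, rtol=1e-12)

    def test_uniform_scaling(self):
        sample = DemodulatedPair(np.full((2, 2), 1.0), np.zeros((2, 2)), fx=0.0)
        ref = DemodulatedPair(np.full((2, 2), 2.0), np.zeros((2, 2)), fx=0.0)
        out = flat_field_correct(sample, ref, reference_reflectance=0.99)
        np.testing.assert_allclose(out.dc, 0.495, rtol=1e-12)

    def test_gradient_nonuniformity_removed(self):
        """A non-uniform source gradient divides out to a flat field."""
        gradient = np.linspace(0.5, 2.0, 16)[np.newaxis, :].repeat(4, axis=0)
        true_field = 0.7
        sample = DemodulatedPair(true_field * gradient, np.zeros_like(gradient), fx=0.0)
        ref = DemodulatedPair(gradient.copy(), np.zeros_like(gradient), fx=0.0)
        out = flat_field_correct(sample, ref, reference_reflectance=1.0)
        np.testing.assert_allclose(out.dc, true_field, rtol=1e-12)

    def test_zero_reference_pixels_reported(self):
        ref_dc = np.ones((3, 3))
        ref_dc[1, 1] = 0.0
        ref = DemodulatedPair(ref_dc, np.ones((3, 3)), fx=0.0)
        sample = DemodulatedPair(np.ones((3, 3)), np.ones((3, 3)), fx=0.0)
        with pytest.raises(ValueError, match="1 non-positive"):
            flat_field_correct(sample, ref)

    def test_planar_reference_leaves_ac_unchanged(self, rng):
        """A planar (AC-free) reference corrects only the DC channel."""
        dc, ac = _random_fields(rng)
        sample = DemodulatedPair(dc, ac, fx=0.1)
        ref = DemodulatedPair(np.full(dc.shape, 2.0), np.zeros(dc.shape), fx=0.0)
        out = flat_field_correct(sample, ref, reference_reflectance=1.0)
        np.testing.assert_allclose(out.ac, ac)
        np.testing.assert_allclose(out.dc, dc / 2.0)


class TestFrequencySets:
    def test_experiment_frequency_sets(self):
        assert len(EXPERIMENT1_FREQUENCIES) == 18
        assert EXPERIMENT1_FREQUENCIES[0] == pytest.approx(0.01)
        assert EXPERIMENT1_FREQUENCIES[14] == pytest.approx(0.15)
        assert EXPERIMENT1_FREQUENCIES[15:] == (0.20, 0.25, 0.30)
        assert EXPERIMENT2_FREQUENCIES == (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


class TestImageIO:
    def test_save_load_round_trip(self, tmp_path, rng):
        dc, ac = _random_fields(rng)
        ps = synthesize_patterns(dc, ac, fx=0.15, pixel_pitch=0.2)
        sidecar = save_pattern_set(tmp_path, ps)
        loaded = load_pattern_set(sidecar)
        np.testing.assert_allclose(loaded.images, ps.images, rtol=1e-6)
        assert loaded.fx == ps.fx
        assert loaded.pixel_pitch == ps.pixel_pitch

    def test_uint8_png_promoted_to_unit_floats(self, tmp_path):
        import imageio.v3 as iio
        import json

        imgs = (np.full((4, 4), 51, dtype=np.uint8) for _ in range(3))
        names = []
        for i, img in enumerate(imgs):
            name = f"p{i}.png"
            iio.imwrite(tmp_path / name, img)
            names.append(name)
        sidecar = tmp_path / "meta.json"
        sidecar.write_text(
            json.dumps(
                {
                    "images": names,
                    "fx_cycles_per_mm": 0.0,
                    "pixel_pitch_mm": 0.2,
                    "phase_offsets_rad": list(THREE_PHASE_OFFSETS),
                }
            )
        )
        loaded = load_pattern_set(sidecar)
        np.testing.assert_allclose(loaded.images, 51 / 255.0, rtol=1e-12)
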