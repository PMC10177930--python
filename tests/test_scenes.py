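"""Synthetic scene generators: determinism, closed loops, screening."""

import numpy as np
import pytest

from sfdikit import scenes as sc
from sfdikit.contrast import RegionOfInterest, michelson_contrast, peak_valley_ratio
from sfdikit.demodulation import demodulate
from sfdikit.inversion import diffusion_rd, whiteboard_properties
from sfdikit.optics import OpticalProperties, apple_properties

BASE = OpticalProperties(mu_a=0.01, mu_s_prime=1.5)  # nylon-like scatterer
SMALL = (32, 96)


def _uniform_spec(**overrides):
    defaults = dict(
        scene_kind="uniform_slab",
        base_props=apple_properties(630),
        image_shape=SMALL,
        frequencies=(0.1,),
        noise=sc.NOISELESS,
        seed=42,
    )
    defaults.update(overrides)
    return sc.SceneSpec(**defaults)


class TestDeterminism:
    def test_identical_spec_and_seed_render_identical_bytes(self):
        spec = _uniform_spec(noise=sc.NoiseModel())  # default noise on
        a = sc.render_scene(spec)
        b = sc.render_scene(spec)
        for fx in spec.frequencies:
            np.testing.assert_array_equal(
                a.patterns[fx].images, b.patterns[fx].images
            )

    def test_different_seed_changes_noise(self):
        a = sc.render_scene(_uniform_spec(noise=sc.NoiseModel(), seed=1))
        b = sc.render_scene(_uniform_spec(noise=sc.NoiseModel(), seed=2))
        assert not np.array_equal(a.patterns[0.1].images, b.patterns[0.1].images)


class TestUniformClosedLoop:
    def test_noiseless_demodulation_recovers_forward_model(self):
        """Render -> demodulate reproduces the diffusion reflectance exactly
        (up to the known illumination factors)."""
        spec = _uniform_spec()
        scene = sc.render_scene(spec)
        pair = demodulate(scene.patterns[0.1])
        props = spec.base_props
        np.testing.assert_allclose(
            pair.dc, sc.ILLUM_DC * diffusion_rd(props, 0.0), rtol=1e-11
        )
        np.testing.assert_allclose(
            pair.ac, sc.ILLUM_AC * diffusion_rd(props, 0.1), rtol=1e-9
        )

    def test_calibration_against_reference_scene_returns_rd(self):
        from sfdikit.inversion import calibrate_reflectance

        spec = _uniform_spec()
        wb = whiteboard_properties()
        scene = sc.render_scene(spec)
        reference = sc.reference_scene(spec, wb)
        rd = calibrate_reflectance(
            demodulate(scene.patterns[0.1]),
            demodulate(reference.patterns[0.1]),
            wb,
        )
        np.testing.assert_allclose(
            rd.dc, diffusion_rd(spec.base_props, 0.0), rtol=1e-9
        )
        np.testing.assert_allclose(
            rd.ac, diffusion_rd(spec.base_props, 0.1), rtol=1e-8
        )


@pytest.fixture(scope="module")
def phantom():
    spec = sc.SceneSpec(
        scene_kind="buried_cylinders",
        base_props=BASE,
        image_shape=(32, 320),
        pixel_pitch_mm=0.2,
        frequencies=(0.01, 0.04, 0.08, 0.12),
        noise=sc.NOISELESS,
        seed=0,
    )
    return sc.render_scene(spec), spec


class TestBuriedCylinders:
    @staticmethod
    def _hole_contrast(scene, name, fx, channel):
        mask = scene.truth.masks[name]
        rows, cols = np.nonzero(mask)
        roi = RegionOfInterest(
            0, mask.shape[0], max(cols.min() - 8, 0), min(cols.max() + 9, mask.shape[1])
        )
        pair = demodulate(scene.patterns[fx])
        return michelson_contrast(getattr(pair, channel), roi)

    def test_shallow_hole_more_visible_than_deep_hole(self, phantom):
        scene, spec = phantom
        for fx in spec.frequencies:
            c1 = self._hole_contrast(scene, "hole_1", fx, "ac")  # 1 mm deep
            c2 = self._hole_contrast(scene, "hole_2", fx, "ac")  # 11 mm deep
            assert c1 > c2

    def test_contrast_decreases_with_frequency(self, phantom):
        scene, spec = phantom
        for name in ("hole_1", "hole_3", "hole_5"):
            cs = [
                self._hole_contrast(scene, name, fx, "ac")
                for fx in spec.frequencies
            ]
            assert all(a > b for a, b in zip(cs, cs[1:]))

    def test_ground_truth_marks_ink_absorption(self, phantom):
        scene, spec = phantom
        mask = scene.truth.masks["hole_1"]
        assert scene.truth.mu_a_map[mask].mean() == pytest.approx(
            BASE.mu_a * sc.INK_ABSORPTION_FACTOR
        )
        union = np.zeros_like(mask)
        for m in scene.truth.masks.values():
            union |= m
        assert scene.truth.mu_a_map[~union].mean() == pytest.approx(BASE.mu_a)

    def test_overlapping_regions_rejected(self):
        spec = sc.SceneSpec(
            scene_kind="buried_cylinders",
            base_props=BASE,
            geometry={"depths_mm": (1.0, 2.0), "diameters_mm": (30.0, 30.0)},
            image_shape=(16, 100),
            pixel_pitch_mm=0.2,
            frequencies=(0.05,),
            noise=sc.NOISELESS,
        )
        with pytest.raises(ValueError, match="overlap"):
            sc.render_scene(spec)


class TestBarTargetSweep:
    def _spec(self, **overrides):
        defaults = dict(
            scene_kind="bar_target_under_slice",
            base_props=apple_properties(630),
            image_shape=(16, 128),
            pixel_pitch_mm=0.2,
            frequencies=(0.1,),
            noise=sc.NOISELESS,
            seed=7,
        )
        defaults.update(overrides)
        return sc.SceneSpec(**defaults)

    def test_pvr_strictly_decreasing_in_thickness(self):
        roi = RegionOfInterest(0, 16, 16, 112)
        pvrs = []
        for scene in sc.thickness_sweep(self._spec(), [0.0, 0.5, 1.0, 2.0, 3.0]):
            pair = demodulate(scene.patterns[0.1])
            pvrs.append(peak_valley_ratio(pair.dc, roi))
        assert all(a > b for a, b in zip(pvrs, pvrs[1:]))

    def test_zero_thickness_renders_unattenuated_target(self):
        scene = sc.render_scene(self._spec(slice_thickness_mm=0.0))
        pair = demodulate(scene.patterns[0.1])
        bars = scene.truth.masks["bars"]
        np.testing.assert_allclose(pair.dc[bars], sc.ILLUM_DC * 0.05, rtol=1e-10)
        np.testing.assert_allclose(pair.dc[~bars], sc.ILLUM_DC * 0.90, rtol=1e-10)

    def test_sweep_reproducible_and_subseeds_recorded(self):
        spec = self._spec(noise=sc.NoiseModel())
        a = sc.thickness_sweep(spec, [0.5, 1.5])
        b = sc.thickness_sweep(spec, [0.5, 1.5])
        for sa, sb in zip(a, b):
            assert sa.truth.info["sub_seed"] == sb.truth.info["sub_seed"]
            np.testing.assert_array_equal(
                sa.patterns[0.1].images, sb.patterns[0.1].images
            )

    def test_default_thickness_lists_match_protocol(self):
        assert sc.WITH_PEEL_THICKNESSES_MM[0] == 0.9
        assert sc.WITH_PEEL_THICKNESSES_MM[-1] == 4.0
        assert len(sc.WITH_PEEL_THICKNESSES_MM) == 13
        assert sc.WITHOUT_PEEL_THICKNESSES_MM[0] == 0.8
        assert len(sc.WITHOUT_PEEL_THICKNESSES_MM) == 14
        assert all(
            a < b
            for lst in (sc.WITH_PEEL_THICKNESSES_MM, sc.WITHOUT_PEEL_THICKNESSES_MM)
            for a, b in zip(lst, lst[1:])
        )

    def test_empty_thickness_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sc.thickness_sweep(self._spec(), [])

    def test_uncovered_scene_kind_rejected(self):
        with pytest.raises(ValueError, match="covered scenes"):
            sc.thickness_sweep(_uniform_spec(), [1.0])


class TestBruiseScene:
    def _spec(self, thickness=0.0, radius=4.0):
        return sc.SceneSpec(
            scene_kind="bruise_under_slab",
            base_props=apple_properties(630),
            geometry={"radius_mm": radius},
            slice_thickness_mm=thickness,
            image_shape=(64, 64),
            pixel_pitch_mm=0.2,
            frequencies=(0.1,),
            noise=sc.NOISELESS,
            seed=3,
        )

    def test_mask_area_matches_disc_geometry(self):
        radius = 4.0
        scene = sc.bruise_scene(self._spec(radius=radius))
        mask = scene.truth.masks["bruise"]
        pitch = 0.2
        expected = np.pi * radius**2 / pitch**2
        ring = 2 * np.pi * radius / pitch  # one-pixel ring allowance
        assert abs(mask.sum() - expected) <= ring

    def test_ground_truth_records_scattering_factor(self):
        scene = sc.bruise_scene(self._spec())
        assert scene.truth.info["mu_s_prime_factor"] == sc.BRUISE_MU_S_PRIME_FACTOR
        mask = scene.truth.masks["bruise"]
        base = apple_properties(630).mu_s_prime
        assert scene.truth.mu_s_prime_map[mask].mean() == pytest.approx(0.7 * base)

    def test_disc_outside_footprint_rejected(self):
        with pytest.raises(ValueError, match="outside the image footprint"):
            sc.bruise_scene(self._spec(radius=10.0))

    def test_screening_monotone_in_thickness_and_frequency(self):
        """Apparent bruise contrast never grows with burial depth or fx."""
        for fx in (0.05, 0.2):
            contrasts = []
            for t in (0.0, 1.0, 2.0, 4.0):
                spec = sc.SceneSpec(
                    scene_kind="bruise_under_slab",
                    base_props=apple_properties(630),
                    geometry={"radius_mm": 4.0},
                    slice_thickness_mm=t,
                    image_shape=(64, 64),
                    pixel_pitch_mm=0.2,
                    frequencies=(fx,),
                    noise=sc.NOISELESS,
                )
                scene = sc.render_scene(spec)
                pair = demodulate(scene.patterns[fx])
                mask = scene.truth.masks["bruise"]
                contrasts.append(
                    abs(pair.ac[mask].mean() - pair.ac[~mask].mean())
                )
            assert all(a >= b for a, b in zip(contrasts, contrasts[1:]))

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError, match="bruise_under_slab"):
            sc.bruise_scene(_uniform_spec())


class TestNoiseModel:
    def test_quantization_to_8bit_grid(self, rng):
        nm = sc.NoiseModel(0.0, 0.0, 0.0, 8)
        img = rng.uniform(0, 1, (16, 16))
        out = nm.apply(img, rng)
        np.testing.assert_allclose(out * 255, np.round(out * 255), atol=1e-9)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            sc.NoiseModel(gaussian_sigma=-0.1)

    def test_unknown_scene_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown scene_kind"):
            _uniform_spec(scene_kind="mystery")
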