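"""Seeded synthetic scene generators with known ground truth.

Desk-scale analogs of the three bench experiments: a homogeneous slab, a
scattering phantom with ink-filled holes buried at different depths, a
high-contrast bar target covered by an attenuating tissue slice, and a
bruised region (reduced scattering) beneath a covering slab.

Rendering model
---------------
Each pixel is assigned effective top-medium optical properties; its DC and
AC reflectances come from the diffusion forward model at zero frequency and
at the pattern frequency respectively.  A structure buried at depth z
contributes its reflectance contrast attenuated by the round-trip screening
factor ``exp(-2 z / delta'_eff(fx))`` of the covering medium — the
exponential fluence decay applied down and back, with the frequency-
dependent effective penetration depth.  This is a deliberately simple
surrogate for heterogeneous transport: it reproduces the qualitative
structure of depth-resolved imaging (deeper or higher-frequency means less
visible) with exactly known ground truth, but it is not a full radiative
transport solution for layered scenes.

Pattern stacks are synthesised with the three-phase generator, then
corrupted with configurable shot-like and additive Gaussian noise and
optional quantization to a stated bit depth (default: 0.5% additive noise
and 8-bit quantization, emulating an 8-bit camera).  Identical spec + seed
give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import demodulation as dm
from .inversion import diffusion_rd
from .optics import OpticalProperties, effective_penetration_depth

__all__ = [
    "NoiseModel",
    "SceneSpec",
    "GroundTruth",
    "RenderedScene",
    "render_scene",
    "thickness_sweep",
    "bruise_scene",
    "WITH_PEEL_THICKNESSES_MM",
    "WITHOUT_PEEL_THICKNESSES_MM",
]

#: Slice-thickness sweeps (mm) of the covered-target experiment; published
#: thickness ranges are represented by their midpoints.
WITH_PEEL_THICKNESSES_MM: tuple[float, ...] = (
    0.9, 1.05, 1.3, 1.55, 1.65, 1.8, 2.15, 2.45, 2.6, 3.0, 3.4, 3.8, 4.0,
)
WITHOUT_PEEL_THICKNESSES_MM: tuple[float, ...] = (
    0.8, 1.0, 1.25, 1.5, 1.6, 1.8, 2.0, 2.3, 2.55, 2.75, 3.0, 3.2, 3.6, 4.0,
)

#: Absorption multiplier standing in for the diluted-ink hole filling.
INK_ABSORPTION_FACTOR = 50.0

#: Default reduced-scattering multiplier of bruised tissue.
BRUISE_MU_S_PRIME_FACTOR = 0.7

#: Projected illumination amplitudes (fraction of camera full scale) for the
#: DC and AC components; chosen so even a 99%-reflectance target stays below
#: saturation at every phase.
ILLUM_DC = 0.5
ILLUM_AC = 0.45

_SCENE_KINDS = (
    "uniform_slab",
    "buried_cylinders",
    "bar_target_under_slice",
    "bruise_under_slab",
)


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: shot-like, multiplicative, additive, and quantization.

    ``shot_scale`` scales a sqrt(I)-proportional Gaussian term;
    ``multiplicative_sigma`` a relative Gaussian gain error;
    ``gaussian_sigma`` is additive, as a fraction of full scale;
    ``quantization_bits`` rounds intensities to 2^bits - 1 levels
    (None disables quantization).
    """

    shot_scale: float = 0.0
    multiplicative_sigma: float = 0.0
    gaussian_sigma: float = 0.005
    quantization_bits: int | None = 8

    def __post_init__(self) -> None:
        for v in (self.shot_scale, self.multiplicative_sigma, self.gaussian_sigma):
            if v < 0:
                raise ValueError("noise parameters must be >= 0")
        if self.quantization_bits is not None and self.quantization_bits < 1:
            raise ValueError("quantization_bits must be >= 1 or None")

    @property
    def silent(self) -> bool:
        return (
            self.shot_scale == 0.0
            and self.multiplicative_sigma == 0.0
            and self.gaussian_sigma == 0.0
            and self.quantization_bits is None
        )

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = image.copy()
        if self.shot_scale > 0:
            out = out + self.shot_scale * np.sqrt(np.clip(out, 0, None)) * rng.standard_normal(out.shape)
        if self.multiplicative_sigma > 0:
            out = out * (1.0 + self.multiplicative_sigma * rng.standard_normal(out.shape))
        if self.gaussian_sigma > 0:
            out = out + self.gaussian_sigma * rng.standard_normal(out.shape)
        np.clip(out, 0.0, None, out=out)
        if self.quantization_bits is not None:
            levels = 2**self.quantization_bits - 1
            out = np.round(np.clip(out, 0.0, 1.0) * levels) / levels
        return out


NOISELESS = NoiseModel(0.0, 0.0, 0.0, None)


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene.

    ``geometry`` holds scene-kind-specific shape parameters in mm (defaults
    are filled per kind, see the render functions).  ``peel`` optionally
    stacks an extra attenuating layer of given properties and thickness on
    top of covered structures.
    """

    scene_kind: str
    base_props: OpticalProperties
    geometry: dict = field(default_factory=dict)
    slice_thickness_mm: float = 0.0
    peel_props: OpticalProperties | None = None
    peel_thickness_mm: float = 0.0
    pixel_pitch_mm: float = 0.2
    image_shape: tuple[int, int] = (256, 512)
    frequencies: tuple[float, ...] = dm.EXPERIMENT2_FREQUENCIES
    noise: NoiseModel = NoiseModel()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scene_kind not in _SCENE_KINDS:
            raise ValueError(
                f"unknown scene_kind {self.scene_kind!r}; expected one of {_SCENE_KINDS}"
            )
        if self.slice_thickness_mm < 0 or self.peel_thickness_mm < 0:
            raise ValueError("thicknesses must be >= 0")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be > 0")
        if self.peel_props is not None and self.peel_thickness_mm <= 0:
            raise ValueError("a peel layer requires peel_thickness_mm > 0")


@dataclass
class GroundTruth:
    """Per-pixel truth of the effective top medium plus region masks."""

    mu_a_map: np.ndarray
    mu_s_prime_map: np.ndarray
    masks: dict[str, np.ndarray]
    info: dict


@dataclass
class RenderedScene:
    """Pattern stacks per frequency plus the generating ground truth."""

    patterns: dict[float, dm.PatternImageSet]
    truth: GroundTruth
    spec: SceneSpec


def _screening(spec: SceneSpec, depth_mm: float, fx: float) -> float:
    """Round-trip contrast attenuation of a structure buried at depth_mm."""
    kappa = 1.0
    if depth_mm > 0:
        delta = effective_penetration_depth(spec.base_props, fx)
        kappa *= math.exp(-2.0 * depth_mm / delta)
    if spec.peel_props is not None:
        delta_p = effective_penetration_depth(spec.peel_props, fx)
        kappa *= math.exp(-2.0 * spec.peel_thickness_mm / delta_p)
    return kappa


def _structures(spec: SceneSpec):
    """Yield (name, mask, props_or_reflectance, burial_depth_mm) per kind."""
    h, w = spec.image_shape
    geo = spec.geometry
    if spec.scene_kind == "uniform_slab":
        return []
    if spec.scene_kind == "buried_cylinders":
        depths = tuple(geo.get("depths_mm", (1.0, 11.0, 6.0, 4.0, 2.0)))
        diameters = tuple(geo.get("diameters_mm", (8.0, 8.0, 8.0, 4.0, 4.0)))
        if len(depths) != len(diameters):
            raise ValueError("depths_mm and diameters_mm must match in length")
        ink = geo.get("ink_absorption_factor", INK_ABSORPTION_FACTOR)
        props = spec.base_props.with_(mu_a=spec.base_props.mu_a * ink)
        cols = np.arange(w) * spec.pixel_pitch_mm
        width_mm = w * spec.pixel_pitch_mm
        out = []
        for i, (z, d) in enumerate(zip(depths, diameters)):
            center = width_mm * (i + 1) / (len(depths) + 1)
            mask = np.zeros((h, w), dtype=bool)
            mask[:, np.abs(cols - center) <= d / 2] = True
            out.append((f"hole_{i + 1}", mask, props, z))
        return out
    if spec.scene_kind == "bruise_under_slab":
        radius = geo.get("radius_mm", 8.0)
        center = geo.get(
            "center_mm",
            (h * spec.pixel_pitch_mm / 2, w * spec.pixel_pitch_mm / 2),
        )
        factor = geo.get("mu_s_prime_factor", BRUISE_MU_S_PRIME_FACTOR)
        rows = (np.arange(h) + 0.5) * spec.pixel_pitch_mm
        cols = (np.arange(w) + 0.5) * spec.pixel_pitch_mm
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
        if (
            center[0] - radius < 0
            or center[1] - radius < 0
            or center[0] + radius > h * spec.pixel_pitch_mm
            or center[1] + radius > w * spec.pixel_pitch_mm
        ):
            raise ValueError("bruise disc extends outside the image footprint")
        props = spec.base_props.with_(
            mu_s_prime=spec.base_props.mu_s_prime * factor
        )
        return [("bruise", mask, props, spec.slice_thickness_mm)]
    raise AssertionError(spec.scene_kind)  # bar target handled separately


def _check_overlap(structures) -> None:
    total = None
    for _, mask, _, _ in structures:
        if total is None:
            total = mask.astype(int).copy()
        else:
            total += mask.astype(int)
    if total is not None and np.any(total > 1):
        raise ValueError("perturbation regions overlap")


def _bar_target_reflectance(spec: SceneSpec) -> np.ndarray:
    """Reflectance field of the uncovered bar target (white base, dark bars)."""
    h, w = spec.image_shape
    geo = spec.geometry
    period = geo.get("bar_period_mm", 2.0)
    r_white = geo.get("white_reflectance", 0.90)
    r_black = geo.get("black_reflectance", 0.05)
    cols = (np.arange(w) + 0.5) * spec.pixel_pitch_mm
    bars = (cols % period) < (period / 2.0)
    field2d = np.where(bars, r_black, r_white)[np.newaxis, :].repeat(h, axis=0)
    return field2d


def render_scene(spec: SceneSpec) -> RenderedScene:
    """Render three-phase pattern stacks at every requested frequency.

    Returns the stacks keyed by frequency plus the per-pixel ground truth
    (effective top-medium properties, region masks, and the screening factor
    applied to each structure at each frequency).
    """
    h, w = spec.image_shape
    rng = np.random.default_rng(spec.seed)
    mu_a_map = np.full((h, w), spec.base_props.mu_a)
    mu_sp_map = np.full((h, w), spec.base_props.mu_s_prime)
    masks: dict[str, np.ndarray] = {}
    info: dict = {"seed": spec.seed, "screening": {}}

    if spec.scene_kind == "bar_target_under_slice":
        target = _bar_target_reflectance(spec)
        masks["bars"] = target < (target.max() + target.min()) / 2.0
        structures = None
    else:
        structures = _structures(spec)
        _check_overlap(structures)
        for name, mask, props, _ in structures:
            masks[name] = mask
            mu_a_map[mask] = props.mu_a
            mu_sp_map[mask] = props.mu_s_prime

    patterns: dict[float, dm.PatternImageSet] = {}
    for fx in spec.frequencies:
        fields = {}
        for channel_fx, key in ((0.0, "dc"), (fx, "ac")):
            base_rd = diffusion_rd(spec.base_props, channel_fx)
            rd = np.full((h, w), base_rd)
            if spec.scene_kind == "bar_target_under_slice":
                kappa = _screening(spec, spec.slice_thickness_mm, channel_fx)
                rd = base_rd + (target - base_rd) * kappa
                info["screening"].setdefault(key, {})[fx] = kappa
            elif structures:
                for name, mask, props, z in structures:
                    kappa = _screening(spec, z, channel_fx)
                    rd_struct = diffusion_rd(props, channel_fx)
                    rd[mask] = base_rd + (rd_struct - base_rd) * kappa
                    info["screening"].setdefault(key, {}).setdefault(fx, {})[
                        name
                    ] = kappa
            fields[key] = rd
        # modulation amplitude cannot physically exceed the mean reflectance;
        # the per-channel screening surrogate can cross on strongly absorbing
        # structures at intermediate depths, so clip
        fields["ac"] = np.minimum(fields["ac"], fields["dc"])
        clean = dm.synthesize_patterns(
            ILLUM_DC * fields["dc"],
            ILLUM_AC * fields["ac"],
            fx=fx,
            pixel_pitch=spec.pixel_pitch_mm,
        )
        noisy = np.stack([spec.noise.apply(img, rng) for img in clean.images])
        patterns[fx] = dm.PatternImageSet(
            noisy, fx=fx, pixel_pitch=spec.pixel_pitch_mm
        )

    truth = GroundTruth(
        mu_a_map=mu_a_map, mu_s_prime_map=mu_sp_map, masks=masks, info=info
    )
    return RenderedScene(patterns=patterns, truth=truth, spec=spec)


def reference_scene(spec: SceneSpec, reference_props: OpticalProperties) -> RenderedScene:
    """Noiseless uniform reference (whiteboard) rendered with the same
    illumination and frequencies as ``spec`` — the calibration companion."""
    ref_spec = replace(
        spec,
        scene_kind="uniform_slab",
        base_props=reference_props,
        slice_thickness_mm=0.0,
        peel_props=None,
        peel_thickness_mm=0.0,
        noise=NOISELESS,
    )
    return render_scene(ref_spec)


def thickness_sweep(
    spec: SceneSpec, thicknesses_mm: list[float] | tuple[float, ...]
) -> list[RenderedScene]:
    """Render one stack per cover thickness with independent recorded
    sub-seeds (derived deterministically from the spec seed)."""
    if spec.scene_kind not in ("bar_target_under_slice", "bruise_under_slab"):
        raise ValueError(
            "thickness_sweep applies to covered scenes "
            "(bar_target_under_slice or bruise_under_slab)"
        )
    if len(thicknesses_mm) == 0:
        raise ValueError("empty thickness list")
    out = []
    for i, t in enumerate(thicknesses_mm):
        sub_seed = (spec.seed * 1_000_003 + 7919 * i + 1) % 2**31
        sub = replace(spec, slice_thickness_mm=float(t), seed=sub_seed)
        scene = render_scene(sub)
        scene.truth.info["thickness_mm"] = float(t)
        scene.truth.info["sub_seed"] = sub_seed
        out.append(scene)
    return out


def bruise_scene(spec: SceneSpec) -> RenderedScene:
    """Render a bruise-under-slab scene; ground truth records the disc mask
    and the applied reduced-scattering factor."""
    if spec.scene_kind != "bruise_under_slab":
        raise ValueError("bruise_scene requires scene_kind='bruise_under_slab'")
    scene = render_scene(spec)
    scene.truth.info["mu_s_prime_factor"] = spec.geometry.get(
        "mu_s_prime_factor", BRUISE_MU_S_PRIME_FACTOR
    )
    scene.truth.info["cover_thickness_mm"] = spec.slice_thickness_mm
    return scene
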