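"""End-to-end analyses tying the stages together.

Each function is the library form of one CLI command: the Monte Carlo
per-wavelength depth table, the buried-hole contrast study, the
covered-target penetration-depth determination, and the bruise-visibility
study on inverted scattering maps.  All take plain parameters and return
DataFrames/dataclasses; file I/O lives in :mod:`sfdikit.cli`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import contrast as ct
from . import demodulation as dm
from . import inversion as inv
from . import mc
from . import scenes as sc
from .optics import OpticalProperties, load_apple_table

__all__ = [
    "simulate_depth",
    "experiment1_hole_contrast",
    "experiment2_penetration",
    "experiment3_bruise_detection",
    "BruiseVerdict",
]

#: Significance level of the Welch test declaring a bruise visible.
BRUISE_ALPHA = 0.01


def simulate_depth(
    table: pd.DataFrame | None = None,
    n_photons: int = mc.DEFAULT_N_PHOTONS,
    seed: int = mc.DEFAULT_SEED,
    fx: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Sampling-depth quantiles per wavelength plus a summary.

    Uses the packaged apple table when none is given.  The summary reports
    the maximum 75%-of-detected-light depth across wavelengths — the
    simulation's bound on the light penetration depth.
    """
    if table is None:
        table = load_apple_table()
    df = mc.depth_profile_by_wavelength(
        table, n_photons=n_photons, seed=seed, fx=fx
    )
    summary = {
        "max_q75_mm": float(df["q75_mm"].max()),
        "fx": fx,
        "n_photons": n_photons,
        "seed": seed,
    }
    return df, summary


def _hole_roi(mask: np.ndarray, margin: int = 10) -> ct.RegionOfInterest:
    rows, cols = np.nonzero(mask)
    h, w = mask.shape
    return ct.RegionOfInterest(
        row_start=max(int(rows.min()) - margin, 0),
        row_end=min(int(rows.max()) + 1 + margin, h),
        col_start=max(int(cols.min()) - margin, 0),
        col_end=min(int(cols.max()) + 1 + margin, w),
    )


def experiment1_hole_contrast(
    base_props: OpticalProperties,
    frequencies: tuple[float, ...] = dm.EXPERIMENT1_FREQUENCIES,
    image_shape: tuple[int, int] = (128, 512),
    pixel_pitch_mm: float = 0.2,
    noise: sc.NoiseModel | None = None,
    seed: int = 0,
    geometry: dict | None = None,
) -> pd.DataFrame:
    """Per-hole Michelson contrast of DC and AC images across frequencies.

    Renders the buried-hole phantom (ink-filled cylinders at depths of
    1, 11, 6, 4 and 2 mm by default), demodulates each frequency, and scores
    every hole's visibility in both channels.  Returns a tidy frame with
    columns hole, depth_mm, fx, channel, contrast.
    """
    spec = sc.SceneSpec(
        scene_kind="buried_cylinders",
        base_props=base_props,
        geometry=geometry or {},
        image_shape=image_shape,
        pixel_pitch_mm=pixel_pitch_mm,
        frequencies=tuple(frequencies),
        noise=noise if noise is not None else sc.NoiseModel(),
        seed=seed,
    )
    scene = sc.render_scene(spec)
    depths = spec.geometry.get("depths_mm", (1.0, 11.0, 6.0, 4.0, 2.0))
    rows = []
    for fx, patterns in scene.patterns.items():
        pair = dm.demodulate(patterns)
        for i, depth in enumerate(depths):
            name = f"hole_{i + 1}"
            roi = _hole_roi(scene.truth.masks[name])
            for channel, img in (("dc", pair.dc), ("ac", pair.ac)):
                rows.append(
                    {
                        "hole": name,
                        "depth_mm": depth,
                        "fx": fx,
                        "channel": channel,
                        "contrast": ct.michelson_contrast(img, roi),
                    }
                )
    return pd.DataFrame(rows)


def experiment2_penetration(
    slice_props: OpticalProperties,
    thicknesses_mm: tuple[float, ...] = sc.WITH_PEEL_THICKNESSES_MM,
    fx: float = 0.1,
    threshold: float = ct.PVR_THRESHOLD,
    image_shape: tuple[int, int] = (64, 256),
    pixel_pitch_mm: float = 0.2,
    noise: sc.NoiseModel | None = None,
    seed: int = 0,
    peel_props: OpticalProperties | None = None,
    peel_thickness_mm: float = 0.0,
    geometry: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Covered-bar-target penetration depth from a thickness sweep.

    For every slice thickness the bar target is rendered under the cover,
    demodulated, and its DC image scored with Michelson contrast and PVR in
    a central ROI.  The PVR threshold rule then gives the maximum
    penetration depth; a linear contrast-vs-thickness fit over the
    0.9-2.5 mm window is reported alongside.

    Returns (per-thickness frame, summary dict).
    """
    spec = sc.SceneSpec(
        scene_kind="bar_target_under_slice",
        base_props=slice_props,
        geometry=geometry or {},
        image_shape=image_shape,
        pixel_pitch_mm=pixel_pitch_mm,
        frequencies=(fx,),
        noise=noise if noise is not None else sc.NoiseModel(),
        seed=seed,
        peel_props=peel_props,
        peel_thickness_mm=peel_thickness_mm,
    )
    sweep = sc.thickness_sweep(spec, list(thicknesses_mm))
    h, w = image_shape
    roi = ct.RegionOfInterest(h // 4, 3 * h // 4, w // 4, 3 * w // 4)
    rows = []
    for scene in sweep:
        pair = dm.demodulate(scene.patterns[fx])
        c = ct.michelson_contrast(pair.dc, roi)
        pvr = ct.peak_valley_ratio(pair.dc, roi, profile_axis=1)
        rows.append(
            {
                "thickness_mm": scene.truth.info["thickness_mm"],
                "contrast": c,
                "pvr": pvr,
                "penetrated": pvr >= threshold,
            }
        )
    df = pd.DataFrame(rows)
    pvr_series = ct.ThicknessSeries(
        df["thickness_mm"].to_numpy(), df["pvr"].to_numpy(), "pvr"
    )
    decision = ct.penetration_decision(pvr_series, threshold=threshold)
    contrast_series = ct.ThicknessSeries(
        df["thickness_mm"].to_numpy(), df["contrast"].to_numpy(), "contrast"
    )
    try:
        slope, intercept, r2 = ct.contrast_thickness_fit(contrast_series)
    except ValueError:
        slope = intercept = r2 = float("nan")
    summary = {
        "max_penetration_depth_mm": decision.depth_mm,
        "penetrated": decision.penetrated,
        "threshold": threshold,
        "fit_slope_per_mm": slope,
        "fit_intercept": intercept,
        "fit_r_squared": r2,
        "fx": fx,
    }
    return df, summary


@dataclass(frozen=True)
class BruiseVerdict:
    """Visibility of the bruise in the recovered scattering map at one
    cover thickness."""

    thickness_mm: float
    detected: bool
    p_value: float
    mu_s_prime_inside: float
    mu_s_prime_outside: float


def experiment3_bruise_detection(
    base_props: OpticalProperties,
    thicknesses_mm: tuple[float, ...],
    fx: float = 0.1,
    image_shape: tuple[int, int] = (64, 128),
    pixel_pitch_mm: float = 0.2,
    noise: sc.NoiseModel | None = None,
    seed: int = 0,
    alpha: float = BRUISE_ALPHA,
    geometry: dict | None = None,
    lut: inv.ReflectanceLUT | None = None,
) -> list[BruiseVerdict]:
    """Bruise visibility in recovered mu_s' maps versus cover thickness.

    Pipeline per thickness: render the bruise-under-slab scene at one
    modulation frequency, demodulate (DC gives Rd at 0, AC at fx),
    calibrate against a synthetic whiteboard, invert to property maps, and
    compare mu_s' inside the disc mask against the background with a Welch
    two-sample test.  The bruise counts as detected when the mean inside is
    significantly lower at level ``alpha`` (one-sided: bruising reduces
    scattering here by construction).
    """
    geometry = dict(geometry or {})
    geometry.setdefault("radius_mm", 4.0)
    lut = lut or inv.build_lut(
        inv.ForwardModelSettings(frequencies=(0.0, fx), n=base_props.n)
    )
    wb = inv.whiteboard_properties(n=base_props.n)
    spec = sc.SceneSpec(
        scene_kind="bruise_under_slab",
        base_props=base_props,
        geometry=geometry,
        image_shape=image_shape,
        pixel_pitch_mm=pixel_pitch_mm,
        frequencies=(fx,),
        noise=noise if noise is not None else sc.NoiseModel(),
        seed=seed,
    )
    reference = sc.reference_scene(spec, wb)
    ref_pair = dm.demodulate(reference.patterns[fx])
    verdicts = []
    for scene in sc.thickness_sweep(spec, list(thicknesses_mm)):
        pair = dm.demodulate(scene.patterns[fx])
        rd = inv.calibrate_reflectance(pair, ref_pair, wb)
        maps = lut.invert(rd.dc, rd.ac)
        mask = scene.truth.masks["bruise"]
        inside = maps.mu_s_prime_map[mask & maps.valid_mask]
        outside = maps.mu_s_prime_map[(~mask) & maps.valid_mask]
        if inside.size < 3 or outside.size < 3:
            detected, p_value = False, 1.0
        else:
            t_stat, p_two = stats.ttest_ind(inside, outside, equal_var=False)
            # one-sided: bruise lowers mu_s'
            p_value = p_two / 2.0 if t_stat < 0 else 1.0 - p_two / 2.0
            detected = bool(p_value < alpha)
        verdicts.append(
            BruiseVerdict(
                thickness_mm=scene.truth.info["thickness_mm"],
                detected=detected,
                p_value=float(p_value),
                mu_s_prime_inside=float(inside.mean()) if inside.size else math.nan,
                mu_s_prime_outside=float(outside.mean()) if outside.size else math.nan,
            )
        )
    return verdicts
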