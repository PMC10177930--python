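"""Three-phase sinusoidal pattern synthesis, demodulation and flat-field
correction.

Pattern images under three phase-shifted sinusoidal illuminations are

    I_p(x, y) = I_DC(x, y) + I_AC(x, y) * cos(2 pi fx x + phi_p),

with phase offsets phi_p in (-2pi/3, 0, +2pi/3).  Demodulation recovers

    I_DC = (I1 + I2 + I3) / 3
    I_AC = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I1-I3)^2 + (I2-I3)^2).

Coordinate convention: rasters are row-major ``[row, col]``, 0-based; the
modulation axis x runs along columns, physical x = col * pixel_pitch, and the
phase reference is pixel column 0.  A global phase offset is immaterial
(the demodulation is phase-insensitive), so this choice is cosmetic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "THREE_PHASE_OFFSETS",
    "EXPERIMENT1_FREQUENCIES",
    "EXPERIMENT2_FREQUENCIES",
    "PatternImageSet",
    "DemodulatedPair",
    "synthesize_patterns",
    "demodulate",
    "flat_field_correct",
    "save_pattern_set",
    "load_pattern_set",
]

#: Canonical three-phase offsets, radians, in acquisition order.
THREE_PHASE_OFFSETS: tuple[float, float, float] = (
    -2.0 * math.pi / 3.0,
    0.0,
    +2.0 * math.pi / 3.0,
)

#: Spatial-frequency sweep used for the buried-hole (nylon phantom)
#: experiment: 0.01 to 0.15 in 0.01 steps, then 0.20, 0.25, 0.30 mm^-1.
EXPERIMENT1_FREQUENCIES: tuple[float, ...] = tuple(
    round(0.01 * k, 2) for k in range(1, 16)
) + (0.20, 0.25, 0.30)

#: Frequency set used for the slice-covered target and bruise experiments.
EXPERIMENT2_FREQUENCIES: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)

_PHASE_TOL = 1e-12


@dataclass
class PatternImageSet:
    """Three phase-shifted intensity images at one spatial frequency.

    Attributes
    ----------
    images : ndarray, shape (3, H, W)
        Non-negative intensity rasters, one per phase offset.
    fx : float
        Spatial frequency along x (columns), cycles/mm.
    pixel_pitch : float
        Physical size of one pixel, mm.
    phase_offsets : tuple of 3 floats
        Must be (-2pi/3, 0, +2pi/3) in that order.
    """

    images: np.ndarray
    fx: float
    pixel_pitch: float
    phase_offsets: tuple[float, float, float] = THREE_PHASE_OFFSETS

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[0] != 3:
            raise ValueError(
                f"expected three images stacked as (3, H, W), got {self.images.shape}"
            )
        if np.any(self.images < 0):
            raise ValueError("pattern intensities must be >= 0")
        if self.fx < 0:
            raise ValueError("fx must be >= 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        offs = tuple(float(p) for p in self.phase_offsets)
        if len(offs) != 3 or any(
            abs(a - b) > _PHASE_TOL for a, b in zip(offs, THREE_PHASE_OFFSETS)
        ):
            raise ValueError(
                "phase offsets must be (-2pi/3, 0, +2pi/3) in that order"
            )
        self.phase_offsets = offs

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


@dataclass
class DemodulatedPair:
    """Co-registered DC and AC images demodulated at one frequency."""

    dc: np.ndarray
    ac: np.ndarray
    fx: float

    def __post_init__(self) -> None:
        self.dc = np.asarray(self.dc, dtype=float)
        self.ac = np.asarray(self.ac, dtype=float)
        if self.dc.shape != self.ac.shape:
            raise ValueError(
                f"dc and ac must share shape, got {self.dc.shape} vs {self.ac.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.dc.shape


def synthesize_patterns(
    dc_field: np.ndarray,
    ac_field: np.ndarray,
    fx: float,
    pixel_pitch: float,
    phase_offsets: tuple[float, float, float] = THREE_PHASE_OFFSETS,
) -> PatternImageSet:
    """Render the three phase-shifted pattern images of given DC/AC fields.

    Requires ``dc_field >= ac_field >= 0`` elementwise so that intensities
    stay non-negative at every phase.
    """
    dc = np.asarray(dc_field, dtype=float)
    ac = np.asarray(ac_field, dtype=float)
    if dc.shape != ac.shape:
        raise ValueError("dc_field and ac_field must share shape")
    if np.any(ac < 0):
        raise ValueError("ac_field must be >= 0")
    if np.any(ac > dc):
        raise ValueError(
            "ac_field exceeds dc_field somewhere: would produce negative intensity"
        )
    cols = np.arange(dc.shape[-1], dtype=float)
    x = cols * pixel_pitch
    images = np.stack(
        [
            dc + ac * np.cos(2.0 * math.pi * fx * x + phi)[np.newaxis, :]
            for phi in phase_offsets
        ]
    )
    # cos can dip an exact dc==ac pixel a few ulp below zero
    np.clip(images, 0.0, None, out=images)
    return PatternImageSet(images, fx=fx, pixel_pitch=pixel_pitch, phase_offsets=phase_offsets)


def demodulate(patterns: PatternImageSet) -> DemodulatedPair:
    """Recover DC and AC images from a three-phase pattern set."""
    i1, i2, i3 = patterns.images
    dc = (i1 + i2 + i3) / 3.0
    ac = (math.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i1 - i3) ** 2 + (i2 - i3) ** 2
    )
    return DemodulatedPair(dc=dc, ac=ac, fx=patterns.fx)


def flat_field_correct(
    sample: DemodulatedPair,
    reference: DemodulatedPair,
    reference_reflectance: float = 0.99,
    mask: np.ndarray | None = None,
) -> DemodulatedPair:
    """Correct source non-uniformity against a reference (whiteboard) image.

    Each channel becomes ``sample / reference * reference_reflectance`` per
    pixel.  The DC channel is always corrected; the AC channel is corrected
    only when the reference was demodulated at the same frequency and its AC
    raster is strictly positive inside the mask (a planar-illumination
    reference has no AC content), otherwise the sample AC passes through
    unchanged.

    Parameters
    ----------
    mask : bool ndarray, optional
        Analysis mask; reference pixels outside it are ignored.  Defaults to
        the full frame.
    """
    if sample.shape != reference.shape:
        raise ValueError("sample and reference must share shape")
    if mask is None:
        mask = np.ones(sample.shape, dtype=bool)
    bad = np.count_nonzero(reference.dc[mask] <= 0)
    if bad:
        raise ValueError(
            f"reference DC has {bad} non-positive pixels inside the mask"
        )
    dc = np.where(mask, sample.dc / reference.dc * reference_reflectance, sample.dc)
    same_fx = math.isclose(sample.fx, reference.fx, rel_tol=0, abs_tol=1e-12)
    if same_fx and np.all(reference.ac[mask] > 0):
        ac = np.where(mask, sample.ac / reference.ac * reference_reflectance, sample.ac)
    else:
        ac = sample.ac.copy()
    return DemodulatedPair(dc=dc, ac=ac, fx=sample.fx)


# ---------------------------------------------------------------------------
# Image I/O: single-channel TIFF/PNG stacks with a JSON sidecar
# ---------------------------------------------------------------------------

_INT_SCALES = {np.uint8: 255.0, np.uint16: 65535.0}


def _to_float(img: np.ndarray) -> np.ndarray:
    """Promote integer images to float in [0, 1]; floats pass through."""
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    return np.asarray(img, dtype=float)


def save_pattern_set(directory: str | Path, patterns: PatternImageSet, stem: str = "pattern") -> Path:
    """Write the three phase images as 32-bit float TIFFs plus a sidecar.

    Files are ``<stem>_fx<fx>_p<i>.tif`` with ``<stem>_fx<fx>.json`` recording
    fx, pixel pitch and the phase order.  Returns the sidecar path.
    """
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tag = f"{stem}_fx{patterns.fx:.4f}"
    names = []
    for i, img in enumerate(patterns.images):
        name = f"{tag}_p{i}.tif"
        tifffile.imwrite(directory / name, img.astype(np.float32))
        names.append(name)
    sidecar = directory / f"{tag}.json"
    sidecar.write_text(
        json.dumps(
            {
                "images": names,
                "fx_cycles_per_mm": patterns.fx,
                "pixel_pitch_mm": patterns.pixel_pitch,
                "phase_offsets_rad": list(patterns.phase_offsets),
            },
            indent=2,
        )
    )
    return sidecar


def load_pattern_set(sidecar: str | Path) -> PatternImageSet:
    """Read a pattern set written by :func:`save_pattern_set` (or compatible
    8/16-bit PNG/TIFF stacks; integer images are promoted to [0, 1] floats)."""
    import imageio.v3 as iio

    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    imgs = [
        _to_float(iio.imread(sidecar.parent / name)) for name in meta["images"]
    ]
    return PatternImageSet(
        np.stack(imgs),
        fx=float(meta["fx_cycles_per_mm"]),
        pixel_pitch=float(meta["pixel_pitch_mm"]),
        phase_offsets=tuple(meta["phase_offsets_rad"]),
    )
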