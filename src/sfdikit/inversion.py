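"""Diffusion forward model of spatial-frequency-domain reflectance,
reflectance calibration, and per-pixel lookup-table inversion to optical
property maps.

The forward model is the standard diffusion approximation for a spatially
modulated plane wave on a semi-infinite medium.  With transport coefficient
``mu_tr = mu_a + mu_s'``, reduced albedo ``a' = mu_s'/mu_tr`` and the
frequency-generalised attenuation ``mu'_eff = sqrt(mu_eff^2 + (2 pi fx)^2 +
(2 pi fy)^2)``, the diffuse reflectance is

    Rd = 3 A a' / ((mu'_eff/mu_tr + 1)(mu'_eff/mu_tr + 3A)),

where ``A = (1 - R_eff) / (2 (1 + R_eff))`` and the boundary-mismatch
reflection parameter follows the polynomial fit
``R_eff = 0.0636 n + 0.668 + 0.710/n - 1.440/n^2``.

Inversion measures Rd at two spatial frequencies and looks the pair up in a
dense forward-model table: nearest node in reflectance space, then a local
Newton refinement on log-properties.  The measured demodulated images are
first converted to reflectance against a reference target of known
properties (a 99%-reflectance whiteboard in the canonical protocol).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .demodulation import DemodulatedPair
from .optics import DEFAULT_N, OpticalProperties, SpatialFrequency

__all__ = [
    "ForwardModelSettings",
    "PropertyMaps",
    "ReflectanceLUT",
    "diffusion_rd",
    "calibrate_reflectance",
    "build_lut",
    "invert_maps",
    "whiteboard_properties",
]

#: Reflectance-space residual above which a pixel is considered outside the
#: reliable range of the lookup table.
RESIDUAL_THRESHOLD = 0.02


def _boundary_A(n: float) -> float:
    r_eff = 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2
    return (1.0 - r_eff) / (2.0 * (1.0 + r_eff))


def _rd_arrays(mu_a, mu_s_prime, fx: float, n: float):
    """Vectorised diffusion reflectance over broadcastable property arrays."""
    mu_a = np.asarray(mu_a, dtype=float)
    mu_sp = np.asarray(mu_s_prime, dtype=float)
    mu_tr = mu_a + mu_sp
    a_prime = mu_sp / mu_tr
    mu_eff_sq = 3.0 * mu_a * mu_tr
    mu_eff_prime = np.sqrt(mu_eff_sq + (2.0 * math.pi * fx) ** 2)
    A = _boundary_A(n)
    x = mu_eff_prime / mu_tr
    return 3.0 * A * a_prime / ((x + 1.0) * (x + 3.0 * A))


def diffusion_rd(
    props: OpticalProperties, freq: SpatialFrequency | float = 0.0
) -> float:
    """Diffuse reflectance of a semi-infinite medium under modulation.

    Dimensionless, in (0, 1]; equal to 1 only in the perfect-albedo,
    zero-frequency limit; strictly decreasing in spatial frequency and in
    mu_a.
    """
    if props.mu_s_prime <= 0:
        raise ValueError("diffusion_rd requires mu_s_prime > 0")
    f = freq.fx if isinstance(freq, SpatialFrequency) else float(freq)
    if isinstance(freq, SpatialFrequency) and freq.fy != 0.0:
        f = math.hypot(freq.fx, freq.fy)
    return float(_rd_arrays(props.mu_a, props.mu_s_prime, f, props.n))


def whiteboard_properties(
    reflectance: float = 0.99, mu_s_prime: float = 2.0, n: float = DEFAULT_N
) -> OpticalProperties:
    """Effective properties of a calibrated diffuse reference target.

    Solves the forward model for the absorption that yields the calibrated
    planar reflectance (default 99%) at the given reduced scattering.
    """
    if not 0 < reflectance < 1:
        raise ValueError("reference reflectance must lie in (0, 1)")

    def f(log_mu_a: float) -> float:
        return (
            float(_rd_arrays(10.0**log_mu_a, mu_s_prime, 0.0, n)) - reflectance
        )

    log_mu_a = brentq(f, -12.0, 0.0)
    return OpticalProperties(mu_a=10.0**log_mu_a, mu_s_prime=mu_s_prime, n=n)


def calibrate_reflectance(
    sample: DemodulatedPair,
    reference: DemodulatedPair,
    reference_props: OpticalProperties,
) -> DemodulatedPair:
    """Convert demodulated intensities to diffuse reflectance rasters.

    Per pixel and channel: ``Rd_sample = I_sample / I_reference *
    Rd_model(reference_props, fx)`` with fx = 0 for the DC channel and the
    acquisition frequency for the AC channel.  Sample and reference must be
    imaged at the same frequency and geometry.
    """
    if sample.shape != reference.shape:
        raise ValueError("sample and reference must share shape")
    if np.any(reference.dc <= 0) or np.any(reference.ac <= 0):
        raise ValueError("reference rasters must be strictly positive")
    rd_dc = diffusion_rd(reference_props, 0.0)
    rd_ac = diffusion_rd(reference_props, sample.fx)
    return DemodulatedPair(
        dc=sample.dc / reference.dc * rd_dc,
        ac=sample.ac / reference.ac * rd_ac,
        fx=sample.fx,
    )


@dataclass(frozen=True)
class ForwardModelSettings:
    """Grid and frequencies for the two-frequency lookup-table inversion.

    Defaults: DC plus 0.1 cycles/mm (both inside the experimental frequency
    sets), 256 x 256 log-spaced nodes over mu_a in [0.001, 0.5] mm^-1 and
    mu_s' in [0.1, 5.0] mm^-1.
    """

    n: float = DEFAULT_N
    frequencies: tuple[float, float] = (0.0, 0.1)
    mu_a_range: tuple[float, float] = (1e-3, 0.5)
    mu_s_prime_range: tuple[float, float] = (0.1, 5.0)
    grid_shape: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        f1, f2 = self.frequencies
        if f1 == f2:
            raise ValueError("the two inversion frequencies must be distinct")
        for lo, hi in (self.mu_a_range, self.mu_s_prime_range):
            if not 0 < lo < hi:
                raise ValueError("grid ranges must be positive and ordered")
        if min(self.grid_shape) < 8:
            raise ValueError("grid too coarse for inversion")


@dataclass
class PropertyMaps:
    """Per-pixel recovered optical properties and the fit residual.

    ``residual_map`` is the Euclidean distance in (Rd1, Rd2) space between
    the measurement and the forward model at the recovered properties;
    pixels with residual above the threshold are flagged in ``valid_mask``.
    """

    mu_a_map: np.ndarray
    mu_s_prime_map: np.ndarray
    residual_map: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            self.mu_a_map.shape,
            self.mu_s_prime_map.shape,
            self.residual_map.shape,
            self.valid_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError("all maps must share shape")
        if np.any(self.residual_map < 0):
            raise ValueError("residuals must be >= 0")


@dataclass
class ReflectanceLUT:
    """Dense forward-model table (Rd at f1, Rd at f2) -> (mu_a, mu_s')."""

    settings: ForwardModelSettings
    mu_a_nodes: np.ndarray
    mu_s_prime_nodes: np.ndarray
    rd1: np.ndarray  # shape (n_mu_a, n_mu_s)
    rd2: np.ndarray
    _tree: cKDTree = field(repr=False)

    def invert(
        self,
        rd_low: np.ndarray,
        rd_high: np.ndarray,
        residual_threshold: float = RESIDUAL_THRESHOLD,
        refine: bool = True,
    ) -> PropertyMaps:
        return invert_maps(rd_low, rd_high, self, residual_threshold, refine)


def build_lut(settings: ForwardModelSettings | None = None) -> ReflectanceLUT:
    """Evaluate the forward model on the property grid and index it.

    Checks invertibility on the interior: the Jacobian determinant of
    (Rd1, Rd2) with respect to (log mu_a, log mu_s') must keep one sign;
    degenerate cells trigger a build-time warning listing their count.
    """
    settings = settings or ForwardModelSettings()
    n1, n2 = settings.grid_shape
    mu_a = np.logspace(*np.log10(settings.mu_a_range), n1)
    mu_sp = np.logspace(*np.log10(settings.mu_s_prime_range), n2)
    A, S = np.meshgrid(mu_a, mu_sp, indexing="ij")
    f1, f2 = settings.frequencies
    rd1 = _rd_arrays(A, S, f1, settings.n)
    rd2 = _rd_arrays(A, S, f2, settings.n)

    # invertibility check on interior cells
    d1a, d1s = np.gradient(rd1)
    d2a, d2s = np.gradient(rd2)
    det = d1a * d2s - d1s * d2a
    interior = det[1:-1, 1:-1]
    sign = np.sign(np.median(interior))
    bad = int(np.count_nonzero(sign * interior <= 0))
    if bad:
        warnings.warn(
            f"forward-model table has {bad} degenerate/non-monotone interior "
            "cells; inversion may be ambiguous there",
            RuntimeWarning,
            stacklevel=2,
        )
    pts = np.column_stack([rd1.ravel(), rd2.ravel()])
    return ReflectanceLUT(
        settings=settings,
        mu_a_nodes=mu_a,
        mu_s_prime_nodes=mu_sp,
        rd1=rd1,
        rd2=rd2,
        _tree=cKDTree(pts),
    )


def invert_maps(
    rd_low: np.ndarray,
    rd_high: np.ndarray,
    lut: ReflectanceLUT,
    residual_threshold: float = RESIDUAL_THRESHOLD,
    refine: bool = True,
) -> PropertyMaps:
    """Per-pixel lookup of (mu_a, mu_s') from two co-registered reflectance
    rasters (at the table's low and high frequency).

    Nearest forward-model node per pixel, then one damped Newton step on
    (log mu_a, log mu_s') using finite-difference Jacobians, clamped to the
    grid.  The residual map is the reflectance-space distance between the
    measurement and the forward model at the recovered properties.
    """
    rd_low = np.asarray(rd_low, dtype=float)
    rd_high = np.asarray(rd_high, dtype=float)
    if rd_low.shape != rd_high.shape:
        raise ValueError(
            f"reflectance rasters must share shape, got {rd_low.shape} vs {rd_high.shape}"
        )
    shape = rd_low.shape
    q = np.column_stack([rd_low.ravel(), rd_high.ravel()])
    _, idx = lut._tree.query(q)
    n1, n2 = lut.rd1.shape
    ia, is_ = np.unravel_index(idx, (n1, n2))

    log_a = np.log(lut.mu_a_nodes)[ia]
    log_s = np.log(lut.mu_s_prime_nodes)[is_]

    if refine:
        # one Newton step in log-property space, finite-difference Jacobian
        h_a = math.log(lut.mu_a_nodes[1] / lut.mu_a_nodes[0])
        h_s = math.log(
            lut.mu_s_prime_nodes[1] / lut.mu_s_prime_nodes[0]
        )
        f1, f2 = lut.settings.frequencies
        n = lut.settings.n

        def fwd(la, ls):
            return (
                _rd_arrays(np.exp(la), np.exp(ls), f1, n),
                _rd_arrays(np.exp(la), np.exp(ls), f2, n),
            )

        r1, r2 = fwd(log_a, log_s)
        r1a, r2a = fwd(log_a + h_a, log_s)
        r1s, r2s = fwd(log_a, log_s + h_s)
        j11 = (r1a - r1) / h_a
        j12 = (r1s - r1) / h_s
        j21 = (r2a - r2) / h_a
        j22 = (r2s - r2) / h_s
        det = j11 * j22 - j12 * j21
        det = np.where(np.abs(det) < 1e-30, np.nan, det)
        e1 = q[:, 0] - r1
        e2 = q[:, 1] - r2
        da = (j22 * e1 - j12 * e2) / det
        ds = (-j21 * e1 + j11 * e2) / det
        # clamp to one cell so a bad Jacobian cannot throw the pixel far off
        da = np.clip(np.nan_to_num(da), -h_a, h_a)
        ds = np.clip(np.nan_to_num(ds), -h_s, h_s)
        log_a = np.clip(
            log_a + da,
            math.log(lut.mu_a_nodes[0]),
            math.log(lut.mu_a_nodes[-1]),
        )
        log_s = np.clip(
            log_s + ds,
            math.log(lut.mu_s_prime_nodes[0]),
            math.log(lut.mu_s_prime_nodes[-1]),
        )

    mu_a = np.exp(log_a)
    mu_sp = np.exp(log_s)
    r1 = _rd_arrays(mu_a, mu_sp, lut.settings.frequencies[0], lut.settings.n)
    r2 = _rd_arrays(mu_a, mu_sp, lut.settings.frequencies[1], lut.settings.n)
    residual = np.hypot(q[:, 0] - r1, q[:, 1] - r2)
    in_range = (
        (q[:, 0] >= lut.rd1.min())
        & (q[:, 0] <= lut.rd1.max())
        & (q[:, 1] >= lut.rd2.min())
        & (q[:, 1] <= lut.rd2.max())
    )
    return PropertyMaps(
        mu_a_map=mu_a.reshape(shape),
        mu_s_prime_map=mu_sp.reshape(shape),
        residual_map=residual.reshape(shape),
        valid_mask=(in_range & (residual <= residual_threshold)).reshape(shape),
    )
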