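"""Diffusion-theory optics for semi-infinite turbid media.

Closed-form quantities used throughout the package: the effective
attenuation coefficient, the diffuse light penetration depth
``delta = 1/mu_eff``, its spatial-frequency generalisation
``delta'_eff = 1/sqrt(mu_eff^2 + (2 pi fx)^2 + (2 pi fy)^2)``, the photon
mean free path, and the exponential fluence decay with depth.

Conventions
-----------
All lengths are in millimetres and all attenuation coefficients in mm^-1.
Wavelengths (nm) are labels attached to property rows, never operands.
Quantities that diverge (e.g. the penetration depth of a non-absorbing
medium) raise :class:`NonFiniteDepthError` instead of returning inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "OpticalProperties",
    "SpatialFrequency",
    "FluenceParameters",
    "NonFiniteDepthError",
    "effective_attenuation",
    "penetration_depth",
    "effective_penetration_depth",
    "mean_free_path",
    "fluence_at_depth",
    "load_apple_table",
    "apple_properties",
]

#: Default scattering anisotropy for fruit flesh.  Together with the
#: published ranges mu_a 0.01-0.05 mm^-1 and mu_s 9-28 mm^-1 it reproduces
#: both the 1.5-6.0 mm diffuse penetration-depth window and a ~100 um mean
#: free path, so it is used wherever g is not supplied.
DEFAULT_G = 0.9

#: Default tissue refractive index (typical fruit flesh), used only by the
#: boundary-sensitive models (Monte Carlo, diffusion reflectance).
DEFAULT_N = 1.35

_REL_TOL = 1e-9


class NonFiniteDepthError(ValueError):
    """A depth/length formula diverges for the given inputs (e.g. mu_a = 0)."""


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one homogeneous medium at one wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1 (>= 0).
    mu_s : float, optional
        Scattering coefficient, mm^-1.  May be omitted when ``mu_s_prime``
        is given; it is then derived as ``mu_s_prime / (1 - g)``.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering angle),
        in [0, 1).
    n : float
        Refractive index of the medium (>= 1).
    mu_s_prime : float, optional
        Reduced scattering coefficient ``mu_s * (1 - g)``, mm^-1 (> 0).
        Derived from ``mu_s`` and ``g`` when omitted.
    """

    mu_a: float
    mu_s: float | None = None
    g: float = DEFAULT_G
    n: float = DEFAULT_N
    mu_s_prime: float | None = None

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if not 0 <= self.g < 1:
            raise ValueError(f"g must lie in [0, 1), got {self.g}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.mu_s is None and self.mu_s_prime is None:
            raise ValueError("one of mu_s or mu_s_prime is required")
        if self.mu_s is not None and self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if self.mu_s_prime is None:
            object.__setattr__(self, "mu_s_prime", self.mu_s * (1.0 - self.g))
        elif self.mu_s is None:
            object.__setattr__(self, "mu_s", self.mu_s_prime / (1.0 - self.g))
        else:
            expect = self.mu_s * (1.0 - self.g)
            if not math.isclose(self.mu_s_prime, expect, rel_tol=_REL_TOL):
                raise ValueError(
                    f"inconsistent properties: mu_s*(1-g) = {expect!r} but "
                    f"mu_s_prime = {self.mu_s_prime!r}"
                )
        # mu_s_prime = 0 (pure absorber) is admitted: the depth formulas
        # remain well defined there; models that need scattering check it
        if self.mu_s_prime < 0:
            raise ValueError(f"mu_s_prime must be >= 0, got {self.mu_s_prime}")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, mm^-1."""
        return self.mu_a + self.mu_s

    @property
    def mu_tr(self) -> float:
        """Transport coefficient mu_a + mu_s', mm^-1."""
        return self.mu_a + self.mu_s_prime

    def with_(self, **changes) -> "OpticalProperties":
        """Copy with selected fields replaced (mu_s/mu_s_prime re-derived)."""
        fields = {"mu_a": self.mu_a, "g": self.g, "n": self.n}
        if "mu_s" in changes and "mu_s_prime" not in changes:
            fields["mu_s"] = changes.pop("mu_s")
        elif "mu_s_prime" in changes and "mu_s" not in changes:
            fields["mu_s_prime"] = changes.pop("mu_s_prime")
        else:
            fields["mu_s_prime"] = self.mu_s_prime
        fields.update(changes)
        return OpticalProperties(**fields)


@dataclass(frozen=True)
class SpatialFrequency:
    """Spatial frequency of the projected sinusoid, cycles per mm."""

    fx: float
    fy: float = 0.0

    def __post_init__(self) -> None:
        if self.fx < 0 or self.fy < 0:
            raise ValueError(f"spatial frequencies must be >= 0, got {self}")

    @property
    def k_squared(self) -> float:
        """(2 pi fx)^2 + (2 pi fy)^2, the squared modulation wavenumber."""
        return (2.0 * math.pi * self.fx) ** 2 + (2.0 * math.pi * self.fy) ** 2


@dataclass(frozen=True)
class FluenceParameters:
    """Scaling of the sub-surface fluence: incident irradiance and the
    backscatter-dependent scalar multiplying the exponential decay."""

    phi_0: float = 1.0
    k_backscatter: float = 1.0

    def __post_init__(self) -> None:
        if self.phi_0 < 0:
            raise ValueError("phi_0 must be >= 0")
        if self.k_backscatter <= 0:
            raise ValueError("k_backscatter must be > 0")


def _as_frequency(freq: SpatialFrequency | float) -> SpatialFrequency:
    if isinstance(freq, SpatialFrequency):
        return freq
    return SpatialFrequency(float(freq))


def effective_attenuation(props: OpticalProperties) -> float:
    """Effective attenuation coefficient mu_eff = sqrt(3 mu_a (mu_a + mu_s')).

    Zero if and only if the medium does not absorb.
    """
    return math.sqrt(3.0 * props.mu_a * (props.mu_a + props.mu_s_prime))


def penetration_depth(props: OpticalProperties) -> float:
    """Diffuse light penetration depth delta = 1 / mu_eff, mm.

    Strictly decreasing in both mu_a and mu_s'.

    Raises
    ------
    NonFiniteDepthError
        If ``mu_a == 0`` (the depth diverges).
    """
    mu_eff = effective_attenuation(props)
    if mu_eff == 0.0:
        raise NonFiniteDepthError(
            "penetration depth is infinite for a non-absorbing medium (mu_a = 0)"
        )
    return 1.0 / mu_eff


def effective_penetration_depth(
    props: OpticalProperties, freq: SpatialFrequency | float
) -> float:
    """Frequency-dependent penetration depth of modulated illumination, mm.

    delta'_eff = 1 / sqrt(mu_eff^2 + (2 pi fx)^2 + (2 pi fy)^2).  Reduces to
    :func:`penetration_depth` at zero frequency and decreases strictly with
    either frequency component.
    """
    f = _as_frequency(freq)
    mu_prime_sq = effective_attenuation(props) ** 2 + f.k_squared
    if mu_prime_sq == 0.0:
        raise NonFiniteDepthError(
            "effective penetration depth is infinite: mu_a = 0 and fx = fy = 0"
        )
    return 1.0 / math.sqrt(mu_prime_sq)


def mean_free_path(props: OpticalProperties) -> float:
    """Photon mean free path 1 / (mu_a + mu_s), mm.

    Around 0.1 mm for apple flesh (mu_s' >= 1 mm^-1, g ~ 0.9).
    """
    mu_t = props.mu_t
    if mu_t == 0.0:
        raise NonFiniteDepthError("mean free path is infinite: mu_a + mu_s = 0")
    return 1.0 / mu_t


def fluence_at_depth(
    params: FluenceParameters, props: OpticalProperties, z
) -> np.ndarray | float:
    """Sub-surface fluence phi(z) = phi_0 * k * exp(-z / delta).

    ``z`` may be a scalar or array of depths (mm, >= 0).  Valid in the
    diffusive regime, i.e. for z beyond the penetration depth; monotone
    decreasing in z.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise ValueError("depth z must be >= 0")
    delta = penetration_depth(props)
    out = params.phi_0 * params.k_backscatter * np.exp(-z_arr / delta)
    return float(out) if np.isscalar(z) or z_arr.ndim == 0 else out


def load_apple_table() -> pd.DataFrame:
    """Packaged apple-flesh optical properties at the six imaging wavelengths.

    Returns a DataFrame with columns ``wavelength_nm``, ``mu_a_mm-1`` and
    ``mu_s_prime_mm-1`` (integrating-sphere values for peeled 'Golden Cream
    Delicious' flesh).
    """
    with resources.files("sfdikit.data").joinpath(
        "apple_optical_properties.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def apple_properties(
    wavelength_nm: int, g: float = DEFAULT_G, n: float = DEFAULT_N
) -> OpticalProperties:
    """OpticalProperties for one packaged apple wavelength (550...730 nm)."""
    table = load_apple_table()
    row = table[table["wavelength_nm"] == wavelength_nm]
    if row.empty:
        raise KeyError(
            f"wavelength {wavelength_nm} nm not in packaged table; available: "
            f"{table['wavelength_nm'].tolist()}"
        )
    return OpticalProperties(
        mu_a=float(row["mu_a_mm-1"].iloc[0]),
        mu_s_prime=float(row["mu_s_prime_mm-1"].iloc[0]),
        g=g,
        n=n,
    )
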