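"""Image-quality metrics and the penetration-depth decision rule.

Two metrics quantify whether a bar target is still resolvable beneath an
attenuating tissue slice:

* Michelson contrast ``C_M = (Imax - Imin) / (Imax + Imin)`` over a region
  of interest, and
* the peak-to-valley ratio ``PVR = Ipeak / Ivalley`` of the bar-profile
  intensity, averaged over detected local extrema.

Light is declared to have penetrated a slice when PVR >= threshold
(default 1.2, the empirically tuned criterion); the maximum penetration
depth of a thickness sweep is the largest slice thickness still meeting
the criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RegionOfInterest",
    "ThicknessSeries",
    "PenetrationResult",
    "DegenerateProfileError",
    "michelson_contrast",
    "peak_valley_ratio",
    "penetration_decision",
    "contrast_thickness_fit",
    "PVR_THRESHOLD",
]

#: Penetration criterion on the peak-to-valley ratio.  A slice counts as
#: penetrated when PVR >= this value (ties count as penetrated).
PVR_THRESHOLD = 1.2

#: Slice-thickness window (mm) in which contrast falls approximately
#: linearly with thickness; default range for the linear fit.
LINEAR_FIT_RANGE_MM = (0.9, 2.5)


class DegenerateProfileError(ValueError):
    """The ROI profile has no detectable peaks/valleys."""


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular pixel region, 0-based, half-open intervals."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("ROI indices must be >= 0")
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise ValueError("ROI must be non-empty")

    def validate(self, shape: tuple[int, int]) -> None:
        if self.row_end > shape[0] or self.col_end > shape[1]:
            raise ValueError(f"ROI {self} exceeds image bounds {shape}")

    def extract(self, image: np.ndarray) -> np.ndarray:
        self.validate(image.shape)
        return image[self.row_start : self.row_end, self.col_start : self.col_end]


@dataclass
class ThicknessSeries:
    """A metric (contrast or PVR) measured across slice thicknesses."""

    thicknesses_mm: np.ndarray
    metric_values: np.ndarray
    metric_name: str = "pvr"

    def __post_init__(self) -> None:
        self.thicknesses_mm = np.asarray(self.thicknesses_mm, dtype=float)
        self.metric_values = np.asarray(self.metric_values, dtype=float)
        if self.thicknesses_mm.shape != self.metric_values.shape:
            raise ValueError("thicknesses and metric values must match in length")
        if self.thicknesses_mm.size == 0:
            raise ValueError("empty series")
        if np.any(np.diff(self.thicknesses_mm) <= 0):
            raise ValueError("thicknesses must be strictly increasing")


@dataclass(frozen=True)
class PenetrationResult:
    """Outcome of the PVR threshold rule on a thickness sweep."""

    depth_mm: float
    penetrated: bool
    threshold: float


def michelson_contrast(image: np.ndarray, roi: RegionOfInterest) -> float:
    """Michelson contrast (Imax - Imin)/(Imax + Imin) over the ROI, in [0, 1].

    Invariant under positive intensity scaling.
    """
    values = roi.extract(np.asarray(image, dtype=float))
    i_max = float(values.max())
    i_min = float(values.min())
    if i_max + i_min == 0.0:
        raise ValueError("contrast undefined: Imax + Imin = 0 in ROI")
    if i_max <= 0.0:
        raise ValueError("contrast undefined: ROI intensities all <= 0")
    return (i_max - i_min) / (i_max + i_min)


def _profile_extrema(profile: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima by first-difference sign change.

    Plateaus are collapsed to their first sample.
    """
    d = np.diff(profile)
    sign = np.sign(d)
    # carry the previous non-zero sign through plateaus
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    change = np.nonzero(sign[1:] * sign[:-1] < 0)[0] + 1
    peaks = change[sign[change] < 0]
    valleys = change[sign[change] > 0]
    return peaks, valleys


def peak_valley_ratio(
    image: np.ndarray,
    roi: RegionOfInterest,
    profile_axis: int = 1,
    smooth_window: int = 3,
) -> float:
    """Peak-to-valley ratio of the bar profile inside the ROI.

    The ROI is averaged along the axis perpendicular to the bars to form a
    1-D profile (``profile_axis`` is the axis the profile runs along, i.e.
    the axis across the bars).  A short moving mean suppresses noise for
    *locating* extrema (sign changes of the first differences); each
    peak/valley intensity is then read from the raw profile as the local
    max/min inside the smoothing window, so smoothing never biases the
    amplitudes.  Ipeak / Ivalley are means over all detected extrema.  If
    smoothing flattens every extremum, extrema are re-detected on the raw
    profile directly.

    Invariant under positive intensity scaling; >= 1 whenever every peak
    exceeds every valley.
    """
    if profile_axis not in (0, 1):
        raise ValueError("profile_axis must be 0 (rows) or 1 (columns)")
    values = roi.extract(np.asarray(image, dtype=float))
    profile = values.mean(axis=1 - profile_axis)
    if profile.size < 3:
        raise DegenerateProfileError("profile too short for extrema detection")

    half = smooth_window // 2
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(profile, kernel, mode="valid")
        peaks, valleys = _profile_extrema(smoothed)
        if peaks.size and valleys.size:
            def _local(idx, reduce):
                c = idx + half  # map valid-mode index to raw center
                lo = max(c - half, 0)
                hi = min(c + half + 1, profile.size)
                return reduce(profile[lo:hi])

            i_peak = float(np.mean([_local(i, np.max) for i in peaks]))
            i_valley = float(np.mean([_local(i, np.min) for i in valleys]))
            if i_valley <= 0.0:
                raise ValueError("PVR undefined: valley intensity <= 0")
            return i_peak / i_valley
    peaks, valleys = _profile_extrema(profile)
    if peaks.size and valleys.size:
        i_peak = float(profile[peaks].mean())
        i_valley = float(profile[valleys].mean())
        if i_valley <= 0.0:
            raise ValueError("PVR undefined: valley intensity <= 0")
        return i_peak / i_valley
    raise DegenerateProfileError("no peaks/valleys detected in ROI profile")


def penetration_decision(
    series: ThicknessSeries, threshold: float = PVR_THRESHOLD
) -> PenetrationResult:
    """Maximum penetration depth from a PVR-vs-thickness sweep.

    Returns the largest thickness whose PVR >= threshold (ties count as
    penetrated).  If no thickness meets the criterion the depth is 0 with
    ``penetrated=False``.  A non-monotone crossing (a sub-threshold value
    below the returned depth) triggers a warning; the last up-crossing
    wins.

    Monotone in the threshold: raising it never increases the depth.
    """
    above = series.metric_values >= threshold
    if not above.any():
        return PenetrationResult(depth_mm=0.0, penetrated=False, threshold=threshold)
    last = int(np.nonzero(above)[0][-1])
    if not above[: last + 1].all():
        warnings.warn(
            "PVR series crosses the threshold more than once; using the last "
            "up-crossing",
            RuntimeWarning,
            stacklevel=2,
        )
    return PenetrationResult(
        depth_mm=float(series.thicknesses_mm[last]),
        penetrated=True,
        threshold=threshold,
    )


def contrast_thickness_fit(
    series: ThicknessSeries,
    range_mm: tuple[float, float] = LINEAR_FIT_RANGE_MM,
) -> tuple[float, float, float]:
    """Ordinary least squares of the metric on slice thickness.

    Restricted to thicknesses inside ``range_mm`` (inclusive); needs at
    least three points there.  Returns (slope, intercept, R^2); the slope is
    expected to be negative for contrast-vs-thickness data.
    """
    lo, hi = range_mm
    mask = (series.thicknesses_mm >= lo) & (series.thicknesses_mm <= hi)
    if np.count_nonzero(mask) < 3:
        raise ValueError(
            f"need >= 3 points inside {range_mm} mm, got {np.count_nonzero(mask)}"
        )
    res = stats.linregress(series.thicknesses_mm[mask], series.metric_values[mask])
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
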