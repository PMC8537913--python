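"""Instrument-characterization metrics.

Bead-based lateral resolution (FWHM of 2-D Gaussian fits), illumination
field uniformity, irradiance from power/wavelength/NA, and laser power
stability statistics. These are the quality-control quantities a confocal /
STED facility tracks; here they double as oracles for the simulator
(resolution ordering confocal > STED > tau-STED, etc.).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .synthetic_scene import FWHM_PER_SIGMA

__all__ = [
    "FwhmResult",
    "StabilityStats",
    "MetrologyReport",
    "measure_fwhm",
    "field_uniformity",
    "irradiance",
    "power_stability",
]


@dataclass
class FwhmResult:
    """One bead's fitted spot: refined center (pixels), FWHM (nm, average of
    the two axes and per axis) and fit quality R^2."""

    center: tuple[float, float]
    fwhm: float
    fwhm_y: float
    fwhm_x: float
    r_squared: float


@dataclass
class StabilityStats:
    mean: float
    sd: float
    minimum: float
    maximum: float
    deviation_percent: float


@dataclass
class MetrologyReport:
    """Aggregated instrument metrics with units."""

    fwhm_values: list[FwhmResult] = field(default_factory=list)
    uniformity_percent: float | None = None
    irradiance_kw_cm2: float | None = None
    stability: StabilityStats | None = None

    def fwhm_mean_sem(self) -> tuple[float, float]:
        """Mean and standard error of the per-bead FWHM values (nm)."""
        vals = np.array([r.fwhm for r in self.fwhm_values])
        if vals.size == 0:
            return math.nan, math.nan
        sem = vals.std(ddof=1) / math.sqrt(vals.size) if vals.size > 1 else 0.0
        return float(vals.mean()), float(sem)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------


def _gauss2d(params: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    amp, y0, x0, sy, sx, off = params
    return off + amp * np.exp(
        -((yy - y0) ** 2) / (2 * sy**2) - ((xx - x0) ** 2) / (2 * sx**2)
    )


def measure_fwhm(
    image: np.ndarray,
    approximate_centers: np.ndarray | None = None,
    pixel_size: float = 1.0,
    window: int = 21,
    min_r_squared: float = 0.9,
) -> list[FwhmResult]:
    """Per-bead lateral FWHM by 2-D Gaussian fitting around each peak.

    If ``approximate_centers`` (rows of (y, x) pixel coordinates) is not
    given, peaks are detected on a lightly smoothed copy of the image.
    For each center a ``window`` x ``window`` crop is fit with an elliptical
    Gaussian plus offset; FWHM = 2.3548 sigma * pixel_size per axis, averaged.
    Fits with R^2 below ``min_r_squared`` are excluded. With no detectable
    peak an empty list is returned with a warning (not an error).
    """
    image = np.asarray(image, dtype=float)
    if approximate_centers is None:
        smoothed = gaussian_filter(image, 1.0)
        peaks = peak_local_max(
            smoothed,
            min_distance=max(window // 2, 3),
            threshold_rel=0.2,
            exclude_border=window // 2,
        )
        if peaks.size == 0:
            warnings.warn("no peaks found for FWHM measurement", stacklevel=2)
            return []
        approximate_centers = peaks
    half = window // 2
    results: list[FwhmResult] = []
    for cy, cx in np.asarray(approximate_centers, dtype=float):
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = max(iy - half, 0), min(iy + half + 1, image.shape[0])
        x0, x1 = max(ix - half, 0), min(ix + half + 1, image.shape[1])
        crop = image[y0:y1, x0:x1]
        if crop.size < 9 or crop.max() <= crop.min():
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        p0 = np.array(
            [crop.max() - crop.min(), cy, cx, window / 6.0, window / 6.0, crop.min()]
        )
        lb = [0.0, y0, x0, 0.2, 0.2, -np.inf]
        ub = [np.inf, y1, x1, window, window, np.inf]
        try:
            res = least_squares(
                lambda p: (_gauss2d(p, yy, xx) - crop).ravel(),
                p0,
                bounds=(lb, ub),
                max_nfev=400,
            )
        except ValueError:
            continue
        model = _gauss2d(res.x, yy, xx)
        ss_res = float(np.sum((crop - model) ** 2))
        ss_tot = float(np.sum((crop - crop.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if r2 < min_r_squared:
            continue
        fy = FWHM_PER_SIGMA * abs(res.x[3]) * pixel_size
        fx = FWHM_PER_SIGMA * abs(res.x[4]) * pixel_size
        results.append(
            FwhmResult(
                (float(res.x[1]), float(res.x[2])), (fy + fx) / 2.0, fy, fx, r2
            )
        )
    return results


def field_uniformity(image: np.ndarray, smoothing: int = 3) -> float:
    """Illumination uniformity: 100 x (smoothed minimum / smoothed maximum)
    after median smoothing (default 3x3), reported to one decimal.
    Invariant to global intensity scaling."""
    image = np.asarray(image, dtype=float)
    if image.size == 0 or np.any(image < 0):
        raise ValueError("image must be non-empty and non-negative")
    if not np.any(image > 0):
        raise ValueError("all-zero image: uniformity undefined")
    smoothed = median_filter(image, size=smoothing)
    return round(100.0 * float(smoothed.min()) / float(smoothed.max()), 1)


def irradiance(power: float, wavelength: float, numerical_aperture: float) -> float:
    """Irradiance (kW/cm^2) of ``power`` microwatts focused to a spot of Airy
    radius r = 0.61 lambda / NA (declared spot-area convention):
    I = P / (pi r^2). Linear in power, scales as NA^2 / lambda^2."""
    if power <= 0 or wavelength <= 0 or numerical_aperture <= 0:
        raise ValueError("power, wavelength and NA must all be positive")
    if numerical_aperture > 1.7:
        raise ValueError("non-physical numerical aperture (> 1.7)")
    r_cm = 0.61 * wavelength * 1e-7 / numerical_aperture
    power_kw = power * 1e-9
    return power_kw / (math.pi * r_cm**2)


def power_stability(series) -> StabilityStats:
    """Stability statistics of a (time, power uW) series: mean, SD, min, max
    and deviation % = 100 (max - min) / (2 mean)."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 2:
        powers = arr[:, 1]
    else:
        powers = arr
    if powers.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(powers < 0):
        raise ValueError("negative powers are not physical")
    mean = float(powers.mean())
    sd = float(powers.std(ddof=1))
    pmin, pmax = float(powers.min()), float(powers.max())
    dev = 100.0 * (pmax - pmin) / (2.0 * mean) if mean > 0 else 0.0
    return StabilityStats(mean, sd, pmin, pmax, dev)
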