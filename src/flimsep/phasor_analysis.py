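"""Phasor-plot analysis: transformation, calibration, universal-circle
geometry, fine lifetime separation by ROI and two-component unmixing.

Each pixel's decay histogram is mapped to first-harmonic Fourier coordinates

    g = sum_k c_k cos(n w t_k) / sum_k c_k,   s = sum_k c_k sin(n w t_k) / sum_k c_k

over bin centers t_k (midpoint convention; the half-bin phase this introduces
is absorbed by calibration). Mono-exponential decays lie on the universal
circle (g - 1/2)^2 + s^2 = 1/4; photon-weighted mixtures are linear in
phasor space, which is what makes ROI classification and two-component
unmixing work.

Calibration maps the pooled phasor of a single-lifetime reference acquisition
onto the model point of its known lifetime. The model point is the closed
form of the midpoint-DFT of a bin-sampled wrapped exponential rescaled onto
the universal circle (see :func:`model_phasor`), so that after calibration
noiseless mono-exponential pixels sit on the circle to machine precision at
any number of time bins.
"""

from __future__ import annotations

import cmath
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter

from .synthetic_scene import TCSPCImage

__all__ = [
    "PhasorField",
    "PhasorROI",
    "model_phasor",
    "phasor_transform",
    "calibrate_phasor",
    "tau_from_phasor",
    "roi_from_tau",
    "separate_by_roi",
    "unmix_two_components",
]


@dataclass
class PhasorField:
    """Per-pixel (g, s) coordinates plus photon counts.

    ``omega`` is the first-harmonic angular frequency 2*pi/T in rad/ns;
    ``bin_width`` (ns) is retained so calibration can account for the finite
    TCSPC bin width. (g, s) are NaN where no photons were detected.
    """

    g: np.ndarray
    s: np.ndarray
    photons: np.ndarray
    harmonic: int
    omega: float
    bin_width: float
    calibrated: bool = False
    median_size: int = 1

    def pooled(self) -> tuple[float, float]:
        """Photon-weighted mean (g, s) over all pixels with photons."""
        w = self.photons.astype(float)
        ok = (w > 0) & np.isfinite(self.g) & np.isfinite(self.s)
        tot = w[ok].sum()
        if tot == 0:
            raise ValueError("no photons in field")
        return (
            float(np.sum(w[ok] * self.g[ok]) / tot),
            float(np.sum(w[ok] * self.s[ok]) / tot),
        )


@dataclass
class PhasorROI:
    """Circular phasor-plot region of interest.

    Either an explicit ``center``/``radius`` pair, or a ``target_tau`` (ns)
    with ``tolerance`` (ns) which is converted to a circle centered on the
    universal-circle point of that lifetime when the ROI is applied to a
    field.
    """

    label: str
    center: tuple[float, float] | None = None
    radius: float | None = None
    target_tau: float | None = None
    tolerance: float | None = None

    def __post_init__(self) -> None:
        if self.target_tau is None:
            if self.center is None or self.radius is None:
                raise ValueError("PhasorROI needs center+radius or target_tau")
            if self.radius <= 0:
                raise ValueError("radius must be > 0")
            gx, sy = self.center
            if not (0.0 <= gx <= 1.0 and 0.0 <= sy <= 0.6):
                warnings.warn(
                    f"ROI {self.label!r} center {self.center} outside "
                    "[0,1]x[0,0.6]",
                    stacklevel=2,
                )
        else:
            if self.target_tau <= 0:
                raise ValueError("target_tau must be > 0")
            if not self.tolerance or self.tolerance <= 0:
                raise ValueError("target_tau requires a positive tolerance")

    def resolve(self, omega: float, harmonic: int, bin_width: float) -> "PhasorROI":
        """Return an explicit center/radius ROI for the given field timing."""
        if self.target_tau is None:
            return self
        return roi_from_tau(
            self.target_tau, self.tolerance, omega, harmonic, bin_width, self.label
        )


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def model_phasor(
    tau: float, omega: float, harmonic: int = 1, bin_width: float | None = None
) -> complex:
    """Universal-circle phasor of a mono-exponential lifetime.

    With ``bin_width=None`` this is the continuous closed form
    1 / (1 - i n w tau). With a finite bin width dt the midpoint-DFT of a
    bin-sampled wrapped exponential is used, rescaled by cos(n w dt / 2) so
    that the whole lifetime family lies exactly on the universal circle
    (Re(1/z) = 1); this is the calibration target that absorbs finite-bin
    effects.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    nw = harmonic * omega
    if bin_width is None:
        return 1.0 / (1.0 - 1j * nw * tau)
    phi = nw * bin_width
    b = math.exp(-bin_width / tau)
    z = (1.0 - b) / (1.0 - b * cmath.exp(1j * phi))
    return z * cmath.exp(1j * phi / 2.0) * math.cos(phi / 2.0)


def phasor_transform(
    tcspc: TCSPCImage, harmonic: int = 1, spatial_median: int = 0
) -> PhasorField:
    """Raw (uncalibrated) per-pixel phasor coordinates of a TCSPC stack.

    ``spatial_median`` (odd, >= 3) applies a median filter to g and s (not to
    the photon counts); 0 or 1 disables filtering.
    """
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    optics = tcspc.optics
    t = optics.bin_centers
    ang = harmonic * optics.omega * t
    cosb, sinb = np.cos(ang), np.sin(ang)
    photons = tcspc.counts.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.tensordot(tcspc.counts, cosb, axes=([2], [0])) / photons
        s = np.tensordot(tcspc.counts, sinb, axes=([2], [0])) / photons
    empty = photons == 0
    g = np.where(empty, np.nan, g)
    s = np.where(empty, np.nan, s)
    if spatial_median and spatial_median > 1:
        if spatial_median % 2 == 0:
            raise ValueError("spatial_median must be odd")
        # empty pixels are filled with the pooled centroid before filtering
        # so they do not drag neighboring (g, s) toward the origin
        w = photons.astype(float)
        tot = w[~empty].sum()
        if tot > 0:
            fill_g = float(np.sum(w[~empty] * g[~empty]) / tot)
            fill_s = float(np.sum(w[~empty] * s[~empty]) / tot)
        else:
            fill_g = fill_s = 0.0
        g = median_filter(np.where(empty, fill_g, g), size=spatial_median)
        s = median_filter(np.where(empty, fill_s, s), size=spatial_median)
        g = np.where(empty, np.nan, g)
        s = np.where(empty, np.nan, s)
    return PhasorField(
        g,
        s,
        photons,
        harmonic,
        optics.omega,
        optics.bin_width,
        calibrated=False,
        median_size=spatial_median if spatial_median and spatial_median > 1 else 1,
    )


def calibrate_phasor(
    field: PhasorField, reference: TCSPCImage, reference_tau: float
) -> PhasorField:
    """Calibrate a phasor field against a homogeneous single-lifetime
    reference acquisition.

    The complex rotation/scaling that maps the reference's pooled raw phasor
    onto :func:`model_phasor` of ``reference_tau`` is applied to every pixel.
    This removes the IRF phase/modulation (and the midpoint half-bin phase)
    common to both acquisitions. Raises if the reference modulation is ~0.
    """
    ref_field = phasor_transform(reference, harmonic=field.harmonic)
    g0, s0 = ref_field.pooled()
    z_ref = complex(g0, s0)
    if abs(z_ref) < 1e-6:
        raise ValueError("reference pooled modulation is ~0; cannot calibrate")
    target = model_phasor(
        reference_tau, field.omega, field.harmonic, field.bin_width
    )
    k = target / z_ref
    z = (field.g + 1j * field.s) * k
    return replace(field, g=z.real, s=z.imag, calibrated=True)


def tau_from_phasor(
    point: tuple[float, float], omega: float
) -> tuple[float, float]:
    """Phase and modulation lifetimes (ns) of a phasor point.

    tau_phase = s / (g w); tau_mod = sqrt(1/(g^2+s^2) - 1) / w. Points with
    g <= 0 get NaN phase lifetime; points outside the unit circle get NaN
    modulation lifetime. On the universal circle the two agree.
    """
    g, s = float(point[0]), float(point[1])
    tau_phase = s / (g * omega) if g > 0 else math.nan
    m2 = g * g + s * s
    if 0 < m2 <= 1.0:
        tau_mod = math.sqrt(1.0 / m2 - 1.0) / omega
    elif m2 == 0:
        tau_mod = math.inf
    else:
        tau_mod = math.nan
    return tau_phase, tau_mod


def roi_from_tau(
    tau: float,
    tolerance: float,
    omega: float,
    harmonic: int = 1,
    bin_width: float | None = None,
    label: str = "",
) -> PhasorROI:
    """Circle ROI centered on the universal-circle point of ``tau`` with a
    radius spanning ``tau +/- tolerance`` along the circle."""
    z = model_phasor(tau, omega, harmonic, bin_width)
    z_lo = model_phasor(max(tau - tolerance, 1e-6), omega, harmonic, bin_width)
    z_hi = model_phasor(tau + tolerance, omega, harmonic, bin_width)
    radius = max(abs(z_hi - z_lo) / 2.0, 1e-4)
    return PhasorROI(label or f"tau={tau:g}ns", (z.real, z.imag), radius)


# ---------------------------------------------------------------------------
# fine tau separation and unmixing
# ---------------------------------------------------------------------------


def separate_by_roi(
    field: PhasorField,
    intensity: np.ndarray,
    rois: list[PhasorROI],
    unassigned_policy: str = "discard",
) -> tuple[list[np.ndarray], np.ndarray]:
    """Fine lifetime separation: assign each pixel to the phasor ROI
    containing its (g, s).

    ROIs are priority-ordered (first match wins). With
    ``unassigned_policy='nearest'`` pixels outside every ROI are assigned to
    the nearest ROI center so intensity is conserved; with ``'discard'``
    (default, matching the background-suppression behavior of the method)
    they contribute to no channel. Returns ``(channel_images,
    assignment_map)`` where the assignment map holds the ROI index or -1.
    """
    if not field.calibrated:
        raise ValueError("phasor field must be calibrated before separation")
    if not rois:
        raise ValueError("at least one ROI required")
    if unassigned_policy not in ("discard", "nearest"):
        raise ValueError("unassigned_policy must be 'discard' or 'nearest'")
    resolved = [r.resolve(field.omega, field.harmonic, field.bin_width) for r in rois]
    valid = np.isfinite(field.g) & np.isfinite(field.s)
    assignment = np.full(field.g.shape, -1, dtype=np.int32)
    for i, roi in enumerate(resolved):
        cg, cs = roi.center  # type: ignore[misc]
        dist2 = (field.g - cg) ** 2 + (field.s - cs) ** 2
        hit = valid & (assignment == -1) & (dist2 <= roi.radius**2)  # type: ignore[operator]
        assignment[hit] = i
    if unassigned_policy == "nearest":
        unass = valid & (assignment == -1)
        if np.any(unass):
            centers = np.array([r.center for r in resolved])
            d2 = (
                (field.g[unass, None] - centers[None, :, 0]) ** 2
                + (field.s[unass, None] - centers[None, :, 1]) ** 2
            )
            assignment[unass] = np.argmin(d2, axis=1)
    channels = [np.where(assignment == i, intensity, 0) for i in range(len(resolved))]
    return channels, assignment


def unmix_two_components(
    field: PhasorField,
    intensity: np.ndarray,
    p1: tuple[float, float],
    p2: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Photon fractions of two decay components by orthogonal projection of
    each pixel phasor onto the p1-p2 chord.

    Phasor coordinates of a mixture are photon-weighted means of the
    component phasors, so the position along the chord is linear in photon
    fraction. Returns (f1, f2) images with f1 + f2 = 1, clipped to [0, 1],
    NaN where no photons. Raises on a degenerate (zero-length) chord.
    """
    if not field.calibrated:
        raise ValueError("phasor field must be calibrated before unmixing")
    v = np.array(p2, dtype=float) - np.array(p1, dtype=float)
    n2 = float(v @ v)
    if n2 < 1e-12:
        raise ValueError("degenerate chord: p1 == p2")
    u = ((field.g - p1[0]) * v[0] + (field.s - p1[1]) * v[1]) / n2
    f2 = np.clip(u, 0.0, 1.0)
    f1 = 1.0 - f2
    empty = field.photons == 0
    f1 = np.where(empty, np.nan, f1)
    f2 = np.where(empty, np.nan, f2)
    return f1, f2
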