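"""FRAP mobile-fraction fitting and surface-density determination.

The FRAP readout of interest is the recovered plateau: the pre-bleach
normalized intensity of the central part of the bleached region is fitted with
a single-exponential saturating recovery

    I(t) = alpha * (1 - exp(-k t)),

whose plateau alpha is the mobile fraction; the rate k is a nuisance
parameter. Surface densities come from dividing the mean fluorescence
intensity per um^2 by the mean single-molecule brightness, optionally rescaled
by the area fraction actually occupied by membrane (ER-plasma-membrane
junctions cover only part of the footprint seen in TIRF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .params import ImagingParams, Rect
from .synthetic import RecoveryCurve

__all__ = [
    "FrapFit",
    "DensityEstimate",
    "fit_mobile_fraction",
    "surface_density",
    "measure_frame_density",
    "compute_recovery_curve",
]


@dataclass(frozen=True)
class FrapFit:
    """Bounded single-exponential recovery fit."""

    mobile_fraction: float
    recovery_rate: float
    mobile_fraction_se: float
    recovery_rate_se: float
    residual: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ValueError("mobile_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DensityEstimate:
    """Fluorophore surface density (molecules per um^2)."""

    density: float
    area_fraction: float
    single_molecule_brightness: float

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if not (0.0 < self.area_fraction <= 1.0):
            raise ValueError("area_fraction must be in (0, 1]")


def _recovery(t, alpha, k):
    return alpha * (1.0 - np.exp(-k * t))


def fit_mobile_fraction(curve: RecoveryCurve) -> FrapFit:
    """Fit I(t) = alpha (1 - exp(-k t)) with alpha bounded to [0, 1].

    Needs at least 5 timepoints. Non-convergence on unusable data raises with
    diagnostics instead of returning garbage.
    """
    t = curve.times
    y = curve.normalized_intensity
    if t.size < 5:
        raise ValueError("mobile-fraction fit needs at least 5 timepoints")
    alpha0 = float(np.clip(np.mean(y[max(1, int(0.8 * y.size)):]), 1e-3, 1.0))
    above = np.flatnonzero(y >= 0.5 * alpha0)
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else t[max(1, t.size // 4)]
    k0 = float(np.log(2.0) / max(t_half, np.finfo(float).tiny))
    try:
        popt, pcov = optimize.curve_fit(
            _recovery, t, y, p0=[alpha0, k0],
            bounds=([0.0, 0.0], [1.0, np.inf]), maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise RuntimeError(
            f"recovery fit did not converge (init alpha={alpha0:.3g}, k={k0:.3g}): {exc}"
        ) from exc
    alpha, k = popt
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    resid = float(np.sum((y - _recovery(t, alpha, k)) ** 2))
    return FrapFit(
        mobile_fraction=float(alpha),
        recovery_rate=float(k),
        mobile_fraction_se=float(se[0]),
        recovery_rate_se=float(se[1]),
        residual=resid,
    )


def surface_density(
    mean_intensity_per_area: float,
    single_molecule_brightness: float,
    area_fraction: float = 1.0,
) -> DensityEstimate:
    """Density = mean intensity per um^2 / (single-molecule brightness * area fraction)."""
    if single_molecule_brightness <= 0:
        raise ValueError("single_molecule_brightness must be > 0")
    if not (0.0 < area_fraction <= 1.0):
        raise ValueError("area_fraction must be in (0, 1]")
    if mean_intensity_per_area < 0:
        raise ValueError("mean_intensity_per_area must be >= 0")
    return DensityEstimate(
        density=mean_intensity_per_area / (single_molecule_brightness * area_fraction),
        area_fraction=area_fraction,
        single_molecule_brightness=single_molecule_brightness,
    )


def measure_frame_density(
    frame: np.ndarray,
    imaging: ImagingParams,
    single_molecule_brightness: float,
    area_fraction: float = 1.0,
    region: Rect | None = None,
    background: float | None = None,
) -> DensityEstimate:
    """Surface density from one frame.

    ``background`` is the camera background level in counts per pixel (default:
    the calibrated ``imaging.background_rate * camera_gain``); the mean signal
    above it, per um^2, is divided by the single-molecule brightness.
    """
    sub = frame if region is None else frame[region.to_pixels(imaging.pixel_size, frame.shape)]
    if background is None:
        background = imaging.background_rate * imaging.camera_gain
    per_px = max(float(sub.mean()) - background, 0.0)
    return surface_density(per_px / imaging.pixel_size**2,
                           single_molecule_brightness, area_fraction)


def compute_recovery_curve(
    stack: np.ndarray,
    times,
    roi: Rect,
    imaging: ImagingParams,
    pre_bleach_index: int = 0,
    central_fraction: float = 0.5,
) -> RecoveryCurve:
    """Pre-bleach-normalized recovery of the central part of the bleached region.

    Only the central ``central_fraction`` (by linear dimension) of the ROI is
    integrated, avoiding the rim where diffusion during the bleach pulse blurs
    the step edge. The first post-bleach frame defines I = 0 and the pre-bleach
    frame I = 1.
    """
    if not (0.0 < central_fraction <= 1.0):
        raise ValueError("central_fraction must be in (0, 1]")
    cx = 0.5 * (roi.x0 + roi.x1)
    cy = 0.5 * (roi.y0 + roi.y1)
    hw = 0.5 * central_fraction * roi.width
    hh = 0.5 * central_fraction * roi.height
    sub = Rect(cx - hw, cy - hh, cx + hw, cy + hh).to_pixels(imaging.pixel_size, stack[0].shape)
    means = np.array([float(f[sub].mean()) for f in stack])
    pre = means[pre_bleach_index]
    post = means[pre_bleach_index + 1]
    if pre <= post:
        raise ValueError("pre-bleach intensity must exceed the first post-bleach value")
    rec = means[pre_bleach_index + 1:]
    t = np.asarray(times, dtype=float)
    return RecoveryCurve(times=t, normalized_intensity=(rec - post) / (pre - post))
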