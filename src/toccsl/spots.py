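"""Detection and Gaussian fitting of diffraction-limited single-molecule signals.

The brightness statistic B of a spot is the integrated volume of the fitted
Gaussian above the local background (not the peak amplitude): integrated
brightness is additive over co-diffusing fluorophores, which is what the
autoconvolution stoichiometry analysis requires, and it is robust to small
misfits of the PSF width.

All functions in this module work in pixel units; ``pixel_size`` converts the
reported coordinates and widths to micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

__all__ = [
    "SpotFit",
    "FilterCriteria",
    "detect_spots",
    "fit_gaussian_spot",
    "filter_spots",
    "analyze_frame",
]


@dataclass(frozen=True)
class SpotFit:
    """One fitted diffraction-limited signal.

    Coordinates and sigma are in micrometres (x along columns, y along rows,
    origin at the top-left pixel corner); brightness_B is the integrated
    intensity above background in counts. ``flags`` may contain "edge",
    "overlap" and "failed"; flagged spots are excluded downstream.
    """

    x: float
    y: float
    sigma: float
    brightness_B: float
    background: float
    fit_quality: float
    flags: frozenset = field(default_factory=frozenset)

    @property
    def ok(self) -> bool:
        return not self.flags


@dataclass(frozen=True)
class FilterCriteria:
    """Spot-selection rules applied before the brightness pdf is built."""

    min_separation: float = 4.0  # multiples of psf_sigma
    border_margin: float = 2.0  # pixels
    max_sigma_deviation: float = 0.5  # |sigma/psf_sigma - 1| above this rejects
    min_fit_quality: float = 0.2

    def __post_init__(self) -> None:
        for name in ("min_separation", "border_margin", "max_sigma_deviation", "min_fit_quality"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _robust_sd(values: np.ndarray) -> float:
    """Noise sd from negative deviations only.

    Diffraction-limited signals contribute almost exclusively positive
    deviations to the band-passed image, so the lower half-distribution
    estimates the noise level even when a sizeable area fraction carries
    structure (e.g. the dense unbleached surround of a bleach region).
    """
    med = np.median(values)
    neg = med - values[values < med]
    if neg.size == 0:
        return 0.0
    return 1.4826 * float(np.median(neg))


def bandpass(image: np.ndarray, psf_sigma: float) -> np.ndarray:
    """Matched filter: PSF-scale smoothing minus a coarse background estimate."""
    return gaussian_filter(image, psf_sigma) - gaussian_filter(image, 5.0 * psf_sigma)


def detect_spots(
    image: np.ndarray,
    detection_threshold: float,
    psf_sigma: float,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Candidate spot positions as (row, col) pixel indices.

    Local maxima of the band-passed image exceeding ``detection_threshold``
    noise standard deviations are returned in row-major order. The noise level
    is estimated from the filtered image itself unless ``noise_sd`` is given
    (pass it when only part of the frame is structure-free, e.g. the interior
    of a bleached region).
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    filtered = bandpass(image, psf_sigma)
    noise = _robust_sd(filtered) if noise_sd is None else float(noise_sd)
    if noise == 0.0:
        noise = float(filtered.std()) or np.finfo(float).tiny
    peaks = peak_local_max(
        filtered,
        min_distance=max(1, int(round(2.0 * psf_sigma))),
        threshold_abs=detection_threshold * noise,
        exclude_border=False,
    )
    if peaks.size == 0:
        return peaks.reshape(0, 2)
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))  # row-major, deterministic
    return peaks[order]


def _pixel_gauss_1d(edges: np.ndarray, center: float, sigma: float) -> np.ndarray:
    e = special.erf((edges - center) / (math.sqrt(2.0) * sigma))
    return 0.5 * np.diff(e)


def fit_gaussian_spot(
    image: np.ndarray,
    position,
    psf_sigma_init: float,
    pixel_size: float = 1.0,
    window_halfwidth: int | None = None,
) -> SpotFit:
    """Least-squares fit of a pixel-integrated 2-D Gaussian plus constant background.

    ``position`` is a (row, col) candidate from :func:`detect_spots`. The model
    integrates the Gaussian over each pixel, so the fitted amplitude parameter
    is directly the integrated brightness B. Fit failures set the "failed"
    flag, a window clipped by the image border sets "edge"; no exception is
    raised for degenerate data.
    """
    image = np.asarray(image, dtype=float)
    row, col = int(round(position[0])), int(round(position[1]))
    # 4-sigma half-width: enough background pixels that the B >= 0 boundary
    # does not bias dim spots upward (see docs/methods.md)
    hw = window_halfwidth if window_halfwidth is not None else int(math.ceil(4.0 * psf_sigma_init))
    r0, r1 = row - hw, row + hw + 1
    c0, c1 = col - hw, col + hw + 1
    if r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
        return SpotFit(
            x=(col + 0.5) * pixel_size, y=(row + 0.5) * pixel_size,
            sigma=psf_sigma_init * pixel_size, brightness_B=float("nan"),
            background=float("nan"), fit_quality=0.0, flags=frozenset({"edge"}),
        )
    win = image[r0:r1, c0:c1]
    redge = np.arange(r0, r1 + 1, dtype=float)
    cedge = np.arange(c0, c1 + 1, dtype=float)

    edge_px = np.concatenate([win[0, :], win[-1, :], win[1:-1, 0], win[1:-1, -1]])
    bg0 = float(np.median(edge_px))
    b0 = max(float(win.sum() - bg0 * win.size), 1e-6)
    x0 = col + 0.5
    y0 = row + 0.5

    def model(theta):
        xc, yc, sig, b, bg = theta
        return b * np.outer(
            _pixel_gauss_1d(redge, yc, sig), _pixel_gauss_1d(cedge, xc, sig)
        ) + bg

    def resid(theta):
        return (model(theta) - win).ravel()

    lb = [c0, r0, 0.5 * psf_sigma_init, 0.0, -np.inf]
    ub = [c1, r1, 2.0 * psf_sigma_init, np.inf, np.inf]
    theta0 = [x0, y0, psf_sigma_init, b0, bg0]
    flags = set()
    try:
        res = optimize.least_squares(resid, theta0, bounds=(lb, ub), method="trf")
        xc, yc, sig, b, bg = res.x
        converged = res.success
    except Exception:
        xc, yc, sig, b, bg = x0, y0, psf_sigma_init, 0.0, bg0
        converged = False
    ss_res = float(np.sum((model((xc, yc, sig, b, bg)) - win) ** 2))
    ss_tot = float(np.sum((win - win.mean()) ** 2))
    quality = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0)) if ss_tot > 0 else 0.0
    if not converged or b <= 1e-6:
        flags.add("failed")
    return SpotFit(
        x=xc * pixel_size,
        y=yc * pixel_size,
        sigma=sig * pixel_size,
        brightness_B=float(b),
        background=float(bg),
        fit_quality=quality,
        flags=frozenset(flags),
    )


def filter_spots(
    fits: list[SpotFit],
    criteria: FilterCriteria,
    psf_sigma: float,
    pixel_size: float = 1.0,
    image_shape: tuple[int, int] | None = None,
) -> tuple[list[SpotFit], dict[str, int]]:
    """Apply selection rules; returns accepted spots and per-rule removal counts.

    Rules, in order: pre-flagged (edge/failed), border margin, fit quality,
    PSF-width outliers, and pairwise overlap (both members of any pair closer
    than ``min_separation * psf_sigma`` are removed, since their brightnesses
    would mix). Idempotent: re-filtering the accepted list removes nothing.
    """
    log = {"input": len(fits), "flagged": 0, "border": 0, "quality": 0, "sigma": 0, "overlap": 0}
    sig_um = psf_sigma * pixel_size
    survivors = []
    for f in fits:
        if f.flags:
            log["flagged"] += 1
            continue
        if image_shape is not None:
            m = criteria.border_margin * pixel_size
            if not (
                m <= f.x <= image_shape[1] * pixel_size - m
                and m <= f.y <= image_shape[0] * pixel_size - m
            ):
                log["border"] += 1
                continue
        if f.fit_quality < criteria.min_fit_quality:
            log["quality"] += 1
            continue
        if abs(f.sigma / sig_um - 1.0) > criteria.max_sigma_deviation:
            log["sigma"] += 1
            continue
        survivors.append(f)
    if len(survivors) >= 2 and criteria.min_separation > 0:
        pts = np.array([[f.x, f.y] for f in survivors])
        pairs = cKDTree(pts).query_pairs(criteria.min_separation * sig_um, output_type="ndarray")
        drop = set(pairs.ravel().tolist())
        log["overlap"] = len(drop)
        survivors = [f for i, f in enumerate(survivors) if i not in drop]
    log["accepted"] = len(survivors)
    return survivors, log


def analyze_frame(
    image: np.ndarray,
    psf_sigma_px: float,
    pixel_size: float = 1.0,
    detection_threshold: float = 5.0,
    criteria: FilterCriteria | None = None,
    noise_sd: float | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Detect, fit and filter all spots in one frame.

    Returns the accepted spots as a table (x, y, sigma in um; brightness,
    background, quality) plus the filter log.
    """
    criteria = criteria or FilterCriteria()
    peaks = detect_spots(image, detection_threshold, psf_sigma_px, noise_sd)
    fits = [fit_gaussian_spot(image, p, psf_sigma_px, pixel_size) for p in peaks]
    accepted, log = filter_spots(fits, criteria, psf_sigma_px, pixel_size, image.shape)
    table = pd.DataFrame(
        {
            "x": [f.x for f in accepted],
            "y": [f.y for f in accepted],
            "sigma": [f.sigma for f in accepted],
            "brightness": [f.brightness_B for f in accepted],
            "background": [f.background for f in accepted],
            "quality": [f.fit_quality for f in accepted],
        }
    )
    return table, log
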