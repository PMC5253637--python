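"""Parameter containers shared across the pipeline.

Conventions: positions and lengths in micrometres, times in milliseconds unless a
field says otherwise (diffusion coefficients and rates are per second), image
coordinates 0-based with the origin at the top-left pixel corner, the field of
view the half-open box [0, Lx) x [0, Ly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Rect",
    "PhotophysicsParams",
    "SceneParams",
    "ImagingParams",
    "ProtocolTiming",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in micrometres, half-open: [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("Rect requires x1 > x0 and y1 > y0")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x, y):
        """Vectorized point-in-rectangle test."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)

    def inside(self, other: "Rect") -> bool:
        return (
            self.x0 >= other.x0
            and self.y0 >= other.y0
            and self.x1 <= other.x1
            and self.y1 <= other.y1
        )

    def to_pixels(self, pixel_size: float, shape: tuple[int, int]) -> tuple[slice, slice]:
        """Row/column slices covering the rectangle on a pixel grid."""
        r0 = max(0, int(math.floor(self.y0 / pixel_size)))
        r1 = min(shape[0], int(math.ceil(self.y1 / pixel_size)))
        c0 = max(0, int(math.floor(self.x0 / pixel_size)))
        c1 = min(shape[1], int(math.ceil(self.x1 / pixel_size)))
        return slice(r0, r1), slice(c0, c1)


@dataclass(frozen=True)
class PhotophysicsParams:
    """Fluorophore brightness and photophysics.

    monomer_mean_brightness / monomer_cv parametrize the lognormal law of the
    integrated brightness of one active fluorophore (counts per spot).
    maturation_p is the probability that a genetically fused fluorescent protein
    matured into a fluorescent state; bleach_survival is the probability that an
    active fluorophore survives one bleach exposure inside the bleach region.
    """

    monomer_mean_brightness: float = 100.0
    monomer_cv: float = 0.3
    maturation_p: float = 1.0
    bleach_survival: float = 0.0

    def __post_init__(self) -> None:
        if not self.monomer_mean_brightness > 0:
            raise ValueError("monomer_mean_brightness must be > 0")
        if not self.monomer_cv > 0:
            raise ValueError("monomer_cv must be > 0")
        if not (0.0 < self.maturation_p <= 1.0):
            raise ValueError("maturation_p must be in (0, 1]")
        if not (0.0 <= self.bleach_survival < 1.0):
            raise ValueError("bleach_survival must be in [0, 1)")

    @property
    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the underlying normal for the monomer brightness law."""
        sigma2 = math.log1p(self.monomer_cv**2)
        mu = math.log(self.monomer_mean_brightness) - 0.5 * sigma2
        return mu, math.sqrt(sigma2)

    def draw_monomer_brightness(self, rng: np.random.Generator, size: int) -> np.ndarray:
        mu, sigma = self.lognormal_params
        return rng.lognormal(mu, sigma, size)


@dataclass(frozen=True)
class SceneParams:
    """Ground-truth membrane scene: oligomer mixture, density and mobility.

    true_alpha[N-1] is the fraction of oligomers with N protomers; density is
    oligomers per um^2; exchange_rate is the per-oligomer, per-second rate of
    pairwise subunit-swap events (phenomenological; 0 = kinetically trapped).
    """

    true_alpha: tuple[float, ...] = (1.0,)
    density: float = 1.0
    diffusion_coeff: float = 0.5
    mobile_fraction: float = 1.0
    field_size: tuple[float, float] = (20.0, 20.0)
    exchange_rate: float = 0.0

    def __post_init__(self) -> None:
        alpha = np.asarray(self.true_alpha, dtype=float)
        if alpha.ndim != 1 or alpha.size == 0:
            raise ValueError("true_alpha must be a non-empty 1-D vector")
        if np.any(alpha < 0):
            raise ValueError("true_alpha entries must be >= 0")
        if abs(alpha.sum() - 1.0) > 1e-12:
            raise ValueError("true_alpha must sum to 1 within 1e-12")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be >= 0")
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ValueError("mobile_fraction must be in [0, 1]")
        if not (self.field_size[0] > 0 and self.field_size[1] > 0):
            raise ValueError("field_size must be positive")
        if self.exchange_rate < 0:
            raise ValueError("exchange_rate must be >= 0")

    @property
    def n_max_true(self) -> int:
        return len(self.true_alpha)

    @property
    def field_rect(self) -> Rect:
        return Rect(0.0, 0.0, self.field_size[0], self.field_size[1])

    @property
    def mean_true_size(self) -> float:
        alpha = np.asarray(self.true_alpha)
        return float(np.sum(np.arange(1, alpha.size + 1) * alpha))


@dataclass(frozen=True)
class ImagingParams:
    """Camera and optics model for rendering / analysing frames."""

    pixel_size: float = 0.16
    psf_sigma: float = 0.2
    exposure: float = 3.0
    read_noise_sd: float = 1.5
    background_rate: float = 5.0
    camera_gain: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "psf_sigma", "exposure", "camera_gain"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size


def _default_roi() -> Rect:
    return Rect(6.0, 6.0, 14.0, 14.0)


@dataclass(frozen=True)
class ProtocolTiming:
    """TOCCSL acquisition timing (ms) and bleach geometry.

    Defaults follow the published protocol: 50 ms to the bleach pulse,
    600-800 ms bleach, post-bleach check 40 ms after the pulse, recovery image
    after an adjustable 1,500-12,000 ms; repetitive series run once per minute.
    """

    t_pre: float = 50.0
    t_bleach: float = 700.0
    t_post: float = 40.0
    t_recovery: float = 2000.0
    roi: Rect = field(default_factory=_default_roi)
    n_runs: int = 1
    run_interval: float = 60.0  # seconds between repetitive runs

    def __post_init__(self) -> None:
        for name in ("t_pre", "t_bleach", "t_post", "t_recovery"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t_recovery < self.t_post:
            raise ValueError("t_recovery must be >= t_post")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.run_interval <= 0:
            raise ValueError("run_interval must be > 0")

    def validate_roi(self, field_rect: Rect) -> None:
        if not self.roi.inside(field_rect):
            raise ValueError("bleach ROI must lie strictly inside the field of view")
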