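"""Brightness-distribution stoichiometry by autoconvolution mixture fitting.

The observed single-spot brightness pdf rho(B) of co-diffusing complexes is
modelled as a linear combination of the monomer pdf rho_1(B) and its N-fold
autoconvolutions rho_N(B):

    rho(B) = sum_N alpha_N * rho_N(B),   alpha_N >= 0,  sum_N alpha_N = 1,

where alpha_N is the fraction of spots carrying N co-diffusing active
fluorophores. rho_1 is calibrated from spots recorded after extensive
photobleaching (at most one active fluorophore per complex). Errors on alpha
come from half-sample bootstrap; incomplete fluorophore maturation is undone by
inverting the conditioned binomial thinning model.

Numerical scheme
----------------
Densities live on a uniform grid of 2**12 points from 0 to
(n_max + 1) * max(monomer sample). Empirical densities are built by linear
binning; kernel smoothing is a Gaussian filter with Silverman's bandwidth
computed on the monomer calibration and reused for the mixture sample pdf. The
mixture components are the FFT autoconvolutions of the *pre-smoothing* binned
monomer density, smoothed once with the same kernel, so model and sample pdf
carry exactly the same smoothing and the bias cancels for every order N. The
simplex-constrained least-squares problem is solved exactly by enumerating
candidate support sets (n_max is small), which is deterministic and reproduces
ties; among solutions of equal objective the one with the smallest mean
oligomer size is reported and flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import special
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "BrightnessPDF",
    "OligomerDistribution",
    "UnderSampleWarning",
    "estimate_monomer_pdf",
    "autoconvolve_pdf",
    "fit_mixture",
    "bootstrap_alphas",
    "mean_oligomer_size",
    "correct_maturation",
    "binomial_visible_mixture",
    "MixtureModel",
]

GRID_SIZE = 4096
MIN_CALIBRATION_SAMPLES = 100
RECOMMENDED_FIT_SAMPLES = 750  # established minimum for reliable n-mer fractions


class UnderSampleWarning(UserWarning):
    """Fewer brightness values than the recommended minimum for n-mer fitting."""


@dataclass(frozen=True)
class BrightnessPDF:
    """A normalized probability density of spot brightness on a uniform grid.

    ``raw_density`` (optional) is the pre-smoothing binned empirical density
    used to build autoconvolution components without double smoothing;
    ``bandwidth`` is the Gaussian kernel bandwidth in brightness units.
    """

    grid: np.ndarray
    density: np.ndarray
    label: str = "rho"
    bandwidth: float | None = None
    raw_density: np.ndarray | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or grid.size != dens.size:
            raise ValueError("grid and density must be matching 1-D arrays")
        dx = np.diff(grid)
        if np.any(dx <= 0) or not np.allclose(dx, dx[0], rtol=1e-9):
            raise ValueError("grid must be strictly increasing and uniform")
        if np.any(dens < 0):
            raise ValueError("density must be nonnegative")
        integral = np.trapezoid(dens, grid)
        if abs(integral - 1.0) > 1e-6:
            raise ValueError(f"density must integrate to 1 (got {integral:.8f})")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", dens)

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    @property
    def var(self) -> float:
        m = self.mean
        return float(np.trapezoid((self.grid - m) ** 2 * self.density, self.grid))


@dataclass(frozen=True)
class OligomerDistribution:
    """Fitted fractions alpha_N of co-diffusing active fluorophore counts."""

    alpha: np.ndarray
    n_spots: int
    n_max: int
    alpha_se: np.ndarray | None = None
    objective: float = float("nan")
    degenerate: bool = False
    undersampled: bool = False

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        if np.any(alpha < -1e-12):
            raise ValueError("alpha entries must be >= 0")
        if abs(alpha.sum() - 1.0) > 1e-9:
            raise ValueError("alpha must sum to 1 within 1e-9")
        object.__setattr__(self, "alpha", np.clip(alpha, 0.0, None))

    @property
    def mean_size(self) -> float:
        return mean_oligomer_size(self.alpha)


# ---------------------------------------------------------------------------
# density estimation
# ---------------------------------------------------------------------------


def _linear_bin(samples: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Linear-binning empirical density on a uniform grid (integrates to ~1)."""
    dx = grid[1] - grid[0]
    pos = (samples - grid[0]) / dx
    pos = np.clip(pos, 0.0, grid.size - 1.0 - 1e-12)
    lo = np.floor(pos).astype(int)
    w = pos - lo
    dens = np.zeros(grid.size)
    np.add.at(dens, lo, 1.0 - w)
    np.add.at(dens, lo + 1, w)
    return dens / (samples.size * dx)


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule of thumb, robust scale via min(sd, IQR/1.34)."""
    n = samples.size
    sd = float(np.std(samples, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = float(q75 - q25)
    scale = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    return 0.9 * scale * n ** (-0.2)


def _smooth(density: np.ndarray, bandwidth: float, dx: float) -> np.ndarray:
    """Gaussian kernel smoothing with reflection at the B=0 boundary."""
    if bandwidth <= 0:
        return density.copy()
    return gaussian_filter1d(density, bandwidth / dx, mode="reflect")


def _normalize(density: np.ndarray, grid: np.ndarray) -> np.ndarray:
    density = np.clip(density, 0.0, None)
    return density / np.trapezoid(density, grid)


def estimate_monomer_pdf(
    brightness_samples,
    n_max: int = 5,
    grid_size: int = GRID_SIZE,
    bandwidth: float | None = None,
    negative_policy: str = "reject",
) -> BrightnessPDF:
    """Kernel density estimate of the monomer brightness pdf rho_1.

    The grid spans [0, (n_max + 1) * max(sample)] so that autoconvolutions up
    to order n_max (and one spare) fit without truncation. Negative brightness
    values are rejected or clipped to zero according to ``negative_policy``.
    """
    samples = np.asarray(brightness_samples, dtype=float).ravel()
    if not np.all(np.isfinite(samples)):
        raise ValueError("brightness samples must be finite")
    if samples.size < MIN_CALIBRATION_SAMPLES:
        raise ValueError(
            f"monomer calibration needs >= {MIN_CALIBRATION_SAMPLES} samples, "
            f"got {samples.size}"
        )
    if np.any(samples < 0):
        if negative_policy == "clip":
            warnings.warn("negative brightness values clipped to 0", UserWarning)
            samples = np.clip(samples, 0.0, None)
        else:
            raise ValueError("negative brightness values present (policy 'reject')")
    top = float(samples.max())
    if top <= 0:
        raise ValueError("brightness samples must contain positive values")
    grid = np.linspace(0.0, top * (n_max + 1), grid_size)
    dx = grid[1] - grid[0]
    h = silverman_bandwidth(samples) if bandwidth is None else float(bandwidth)
    h = max(h, dx)  # never narrower than the grid resolution
    raw = _linear_bin(samples, grid)
    density = _normalize(_smooth(raw, h, dx), grid)
    return BrightnessPDF(grid=grid, density=density, label="rho_1", bandwidth=h,
                         raw_density=raw)


def _autoconvolve_density(
    density: np.ndarray, n: int, dx: float, return_lost_mass: bool = False
):
    """n-fold linear autoconvolution via FFT, returned on the original grid.

    Optionally also returns the probability mass of the full convolution that
    falls beyond the grid and is truncated.
    """
    size = density.size
    m = sp_fft.next_fast_len(n * (size - 1) + 1)
    f = sp_fft.rfft(density, m)
    full = np.clip(sp_fft.irfft(f**n, m) * dx ** (n - 1), 0.0, None)
    out = full[:size]
    if not return_lost_mass:
        return out
    lost = float(full[size:].sum() * dx)
    return out, lost


def autoconvolve_pdf(rho1: BrightnessPDF, n: int) -> BrightnessPDF:
    """The pdf of the sum of n independent draws from ``rho1`` (rho_n).

    Computed by FFT-based n-fold autoconvolution on the same grid; raises if
    the grid is too short to hold the support of rho_n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return BrightnessPDF(grid=rho1.grid, density=rho1.density, label="rho_1",
                             bandwidth=rho1.bandwidth, raw_density=rho1.raw_density)
    dens, lost = _autoconvolve_density(rho1.density, n, rho1.dx, return_lost_mass=True)
    if lost > 1e-4:
        raise ValueError(
            f"grid too short to hold the support of rho_{n} "
            f"({lost:.2e} of its mass falls beyond {rho1.grid[-1]:.1f}); extend the grid"
        )
    dens = _normalize(dens, rho1.grid)
    return BrightnessPDF(grid=rho1.grid, density=dens, label=f"rho_{n}")


# ---------------------------------------------------------------------------
# exact simplex-constrained least squares
# ---------------------------------------------------------------------------


def _simplex_lsq(G: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Minimize a'Ga - 2c'a on the probability simplex by support enumeration.

    Returns (alpha, objective, degenerate) where objective omits the constant
    b'b term; degenerate is True when distinct supports tie (the reported
    solution is then the one with the smallest mean size).
    """
    n = G.shape[0]
    best: list[tuple[float, float, np.ndarray]] = []
    scale = max(abs(G).max(), abs(c).max(), 1.0)
    for mask in range(1, 1 << n):
        idx = [i for i in range(n) if mask >> i & 1]
        k = len(idx)
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = G[np.ix_(idx, idx)]
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.append(c[idx], 1.0)
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            continue
        a_s = sol[:k]
        if np.any(a_s < -1e-10):
            continue
        alpha = np.zeros(n)
        alpha[idx] = np.clip(a_s, 0.0, None)
        alpha /= alpha.sum()
        obj = float(alpha @ G @ alpha - 2.0 * c @ alpha)
        msize = float(np.sum((np.arange(n) + 1) * alpha))
        best.append((obj, msize, alpha))
    if not best:
        raise RuntimeError("simplex least squares found no feasible solution")
    best.sort(key=lambda t: (t[0], t[1]))
    obj0, msize0, alpha0 = best[0]
    tol = 1e-10 * scale
    degenerate = any(
        abs(o - obj0) <= tol and not np.allclose(a, alpha0, atol=1e-8)
        for o, _, a in best[1:]
    )
    return alpha0, obj0, degenerate


# ---------------------------------------------------------------------------
# mixture fitting
# ---------------------------------------------------------------------------


class MixtureModel:
    """Precomputed autoconvolution components for repeated mixture fits.

    Builds rho_1..rho_n_max once from a monomer calibration pdf; ``fit`` then
    only bins and smooths the new sample and solves a tiny exact QP, which
    makes bootstrap and per-run series analysis cheap.
    """

    def __init__(self, rho1: BrightnessPDF, n_max: int = 5):
        if n_max < 1:
            raise ValueError("n_max must be >= 1")
        self.rho1 = rho1
        self.n_max = n_max
        self.grid = rho1.grid
        self.dx = rho1.dx
        self.bandwidth = rho1.bandwidth or 0.0
        base = rho1.raw_density if rho1.raw_density is not None else rho1.density
        post_smooth = rho1.raw_density is not None
        comps = []
        for n in range(1, n_max + 1):
            d = base if n == 1 else _autoconvolve_density(base, n, self.dx)
            if post_smooth:
                d = _smooth(d, self.bandwidth, self.dx)
            comps.append(_normalize(d, self.grid))
        self.components = np.column_stack(comps)  # grid x n_max
        self.G = self.components.T @ self.components * self.dx

    def component_pdf(self, n: int) -> BrightnessPDF:
        return BrightnessPDF(grid=self.grid, density=self.components[:, n - 1],
                             label=f"rho_{n}", bandwidth=self.bandwidth)

    def sample_pdf(self, samples: np.ndarray) -> np.ndarray:
        if samples.max() > self.grid[-1]:
            warnings.warn(
                "brightness values beyond the calibration grid were clipped",
                UserWarning,
            )
        raw = _linear_bin(np.clip(samples, 0.0, self.grid[-1]), self.grid)
        return _normalize(_smooth(raw, self.bandwidth, self.dx), self.grid)

    def fit(self, brightness_samples, warn_undersampled: bool = True) -> OligomerDistribution:
        samples = np.asarray(brightness_samples, dtype=float).ravel()
        if samples.size < 1 or not np.all(np.isfinite(samples)):
            raise ValueError("brightness samples must be non-empty and finite")
        undersampled = samples.size < RECOMMENDED_FIT_SAMPLES
        if undersampled and warn_undersampled:
            warnings.warn(
                f"only {samples.size} spots; at least {RECOMMENDED_FIT_SAMPLES} "
                "are recommended for n-mer fractions",
                UnderSampleWarning,
            )
        target = self.sample_pdf(samples)
        c = self.components.T @ target * self.dx
        alpha, obj, degenerate = _simplex_lsq(self.G, c)
        return OligomerDistribution(
            alpha=alpha,
            n_spots=samples.size,
            n_max=self.n_max,
            objective=obj + float(target @ target) * self.dx,
            degenerate=degenerate,
            undersampled=undersampled,
        )


def fit_mixture(brightness_samples, rho1: BrightnessPDF, n_max: int = 5) -> OligomerDistribution:
    """Fit the observed brightness pdf as a simplex combination of rho_1..rho_n_max.

    The sample pdf uses the same grid and kernel bandwidth as the monomer
    calibration; emits :class:`UnderSampleWarning` below 750 spots.
    """
    return MixtureModel(rho1, n_max).fit(brightness_samples)


def bootstrap_alphas(
    brightness_samples,
    rho1: BrightnessPDF,
    n_max: int = 5,
    reps: int = 100,
    frac: float = 0.5,
    seed: int | np.random.Generator = 0,
    divisor: float = math.sqrt(2.0),
) -> np.ndarray:
    """Half-sample bootstrap standard errors of the fitted alpha.

    Random subsamples containing ``frac`` of the data are refitted ``reps``
    times; the reported error is the s.d. across repetitions divided by
    ``divisor`` (default sqrt(2), the correction for 50% subsampling).
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must be in (0, 1)")
    samples = np.asarray(brightness_samples, dtype=float).ravel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = MixtureModel(rho1, n_max)
    m = max(2, int(round(frac * samples.size)))
    alphas = np.empty((reps, n_max))
    for r in range(reps):
        sub = rng.choice(samples, size=m, replace=False)
        alphas[r] = model.fit(sub, warn_undersampled=False).alpha
    return alphas.std(axis=0, ddof=1) / divisor


def mean_oligomer_size(alpha) -> float:
    """Mean number of co-diffusing active fluorophores, sum_N N * alpha_N."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < -1e-12):
        raise ValueError("alpha entries must be >= 0")
    if abs(alpha.sum() - 1.0) > 1e-6:
        raise ValueError("alpha must be normalized (sum to 1)")
    return float(np.sum(np.arange(1, alpha.size + 1) * alpha))


# ---------------------------------------------------------------------------
# maturation correction
# ---------------------------------------------------------------------------


def _visible_thinning_matrix(p: float, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """M[k-1, N-1] = P(k active | true size N, k >= 1); plus visibility weights."""
    M = np.zeros((n_max, n_max))
    vis = np.empty(n_max)
    for n in range(1, n_max + 1):
        k = np.arange(1, n + 1)
        pmf = special.comb(n, k) * p**k * (1 - p) ** (n - k)
        vis[n - 1] = 1.0 - (1.0 - p) ** n
        M[: n, n - 1] = pmf / vis[n - 1]
    return M, vis


def binomial_visible_mixture(alpha_true, maturation_p: float) -> np.ndarray:
    """Forward model: observed visible-spot fractions of active counts k.

    Given true oligomer fractions alpha_N and per-protomer activity probability
    p, visible spots (k >= 1) have active-count fractions
    alpha'_k = sum_N w_N * Binom(k; N, p | k>=1), with w_N the visible-spot
    size composition alpha_N (1 - (1-p)^N) / Z.
    """
    alpha = np.asarray(alpha_true, dtype=float)
    if not (0.0 < maturation_p <= 1.0):
        raise ValueError("maturation_p must be in (0, 1]")
    M, vis = _visible_thinning_matrix(maturation_p, alpha.size)
    w = alpha * vis
    z = w.sum()
    if z <= 0:
        raise ValueError("alpha has no visible mass")
    return M @ (w / z)


def correct_maturation(alpha_observed, maturation_p: float,
                       n_max_true: int | None = None) -> np.ndarray:
    """Invert incomplete-maturation thinning: true oligomer fractions.

    Solves alpha_observed = M w for the visible-spot size composition w on the
    simplex (exactly when the plain linear solve is feasible, otherwise by
    constrained least squares), then rescales by the visibility weights
    1 - (1-p)^N. Observed fractions of co-diffusing *active* fluorophores
    underestimate the true oligomer size whenever p < 1; this undoes that bias.
    """
    alpha_obs = np.asarray(alpha_observed, dtype=float)
    if np.any(alpha_obs < -1e-12) or abs(alpha_obs.sum() - 1.0) > 1e-6:
        raise ValueError("alpha_observed must be a probability vector")
    if not (0.0 < maturation_p <= 1.0):
        raise ValueError("maturation_p must be in (0, 1]")
    n_max = n_max_true if n_max_true is not None else alpha_obs.size
    if n_max != alpha_obs.size:
        raise ValueError("n_max_true must equal len(alpha_observed) (square inversion)")
    M, vis = _visible_thinning_matrix(maturation_p, n_max)
    cond = float(np.linalg.cond(M))
    if cond > 1e8:
        raise ValueError(
            f"thinning inversion ill-conditioned at p={maturation_p} "
            f"(condition number {cond:.3g}); maturation probability too small"
        )
    w = np.linalg.solve(M, alpha_obs)
    if np.any(w < -1e-9):
        w, _, _ = _simplex_lsq(M.T @ M, M.T @ alpha_obs)
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    alpha_true = w / vis
    return alpha_true / alpha_true.sum()
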