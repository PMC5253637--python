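"""Synthetic TIRF imaging, photophysics and TOCCSL protocol simulator.

This module generates the ground-truth data the analysis modules are validated
against: single-spot brightness tables, diffraction-limited image frames with
shot and read noise, full TOCCSL acquisitions (pre-bleach / bleach / post-bleach
/ recovery) of laterally diffusing oligomers, repetitive TOCCSL series with
optional subunit exchange, and FRAP recovery curves.

Model summary
-------------
An oligomer of true size N carries N protomers, each with a fluorophore that is
active with probability ``maturation_p``. The integrated brightness of one
active fluorophore is lognormal with mean ``monomer_mean_brightness`` and
coefficient of variation ``monomer_cv``; a spot with k active fluorophores is
the sum of k independent monomer draws. Oligomers diffuse as rigid units by
per-step Gaussian displacements (reflecting boundaries) with a mobile/immobile
split. A bleach exposure deactivates fluorophores inside the bleach rectangle
(each survives with probability ``bleach_survival``). Subunit exchange is a
Poisson-clocked pairwise swap of one random subunit between two random
oligomers, conserving oligomer sizes, total subunit count and total
active-fluorophore count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .params import ImagingParams, PhotophysicsParams, ProtocolTiming, Rect, SceneParams

__all__ = [
    "OligomerPopulation",
    "ToccslRun",
    "RecoveryCurve",
    "simulate_brightness_samples",
    "render_frame",
    "simulate_toccsl_run",
    "simulate_repetitive_series",
    "simulate_repetitive_brightness_series",
    "simulate_frap_curve",
    "simulate_monomer_calibration_frames",
    "thinned_visible_pmf",
    "exchange_subunits",
]


# ---------------------------------------------------------------------------
# population state
# ---------------------------------------------------------------------------


@dataclass
class OligomerPopulation:
    """Mutable ground-truth state of a membrane scene.

    Arrays are aligned per oligomer: position (um), true size (protomers),
    number of currently active fluorophores, and mobility flag.
    """

    x: np.ndarray
    y: np.ndarray
    size: np.ndarray
    n_active: np.ndarray
    mobile: np.ndarray
    bounds: Rect

    @classmethod
    def sample(
        cls,
        scene: SceneParams,
        photo: PhotophysicsParams,
        rng: np.random.Generator,
        pad: float = 0.0,
    ) -> "OligomerPopulation":
        """Draw a Poisson-distributed population on the (optionally padded) field.

        Padding keeps flux at the image border unbiased: the simulated membrane
        extends beyond the camera field so emitters just outside spill in.
        """
        bounds = Rect(-pad, -pad, scene.field_size[0] + pad, scene.field_size[1] + pad)
        n = int(rng.poisson(scene.density * bounds.area))
        x = rng.uniform(bounds.x0, bounds.x1, n)
        y = rng.uniform(bounds.y0, bounds.y1, n)
        alpha = np.asarray(scene.true_alpha, dtype=float)
        size = rng.choice(np.arange(1, alpha.size + 1), size=n, p=alpha / alpha.sum())
        n_active = rng.binomial(size, photo.maturation_p)
        mobile = rng.random(n) < scene.mobile_fraction
        return cls(x=x, y=y, size=size.astype(np.int64), n_active=n_active.astype(np.int64),
                   mobile=mobile, bounds=bounds)

    @property
    def n_oligomers(self) -> int:
        return self.x.size

    @property
    def visible(self) -> np.ndarray:
        return self.n_active >= 1

    def diffuse(self, dt_s: float, diffusion_coeff: float, rng: np.random.Generator) -> None:
        """Brownian step for mobile oligomers with reflecting boundaries."""
        if dt_s <= 0 or diffusion_coeff <= 0:
            return
        sd = math.sqrt(2.0 * diffusion_coeff * dt_s)
        m = self.mobile
        self.x[m] = _reflect(self.x[m] + rng.normal(0, sd, int(m.sum())),
                             self.bounds.x0, self.bounds.x1)
        self.y[m] = _reflect(self.y[m] + rng.normal(0, sd, int(m.sum())),
                             self.bounds.y0, self.bounds.y1)

    def bleach(self, roi: Rect, survival: float, rng: np.random.Generator) -> None:
        """One bleach exposure: fluorophores of oligomers inside roi survive w.p. survival."""
        inside = roi.contains(self.x, self.y) & (self.n_active > 0)
        if survival == 0.0:
            self.n_active[inside] = 0
        else:
            self.n_active[inside] = rng.binomial(self.n_active[inside], survival)

    def frame_brightness(self, photo: PhotophysicsParams, rng: np.random.Generator) -> np.ndarray:
        """Per-oligomer integrated brightness for one frame (0 for dark oligomers)."""
        out = np.zeros(self.n_oligomers)
        k = self.n_active
        total = int(k.sum())
        if total:
            draws = photo.draw_monomer_brightness(rng, total)
            idx = np.repeat(np.arange(self.n_oligomers), k)
            np.add.at(out, idx, draws)
        return out

    def truth_table(self, brightness: np.ndarray) -> pd.DataFrame:
        vis = self.visible
        return pd.DataFrame(
            {
                "x": self.x[vis],
                "y": self.y[vis],
                "size": self.size[vis],
                "n_active": self.n_active[vis],
                "brightness": brightness[vis],
                "mobile": self.mobile[vis],
            }
        )


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    v = np.mod(v - lo, 2.0 * span)
    v = np.where(v > span, 2.0 * span - v, v)
    # guard against landing exactly on the open upper edge
    return np.minimum(lo + v, np.nextafter(hi, lo))


# ---------------------------------------------------------------------------
# brightness samples (no imaging)
# ---------------------------------------------------------------------------


def _conditional_active_counts(
    sizes: np.ndarray, p: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw k ~ Binomial(N, p) conditioned on k >= 1, vectorized per size class."""
    k = np.zeros(sizes.size, dtype=np.int64)
    for n in np.unique(sizes):
        idx = np.flatnonzero(sizes == n)
        j = np.arange(1, n + 1)
        pmf = special.comb(n, j) * p**j * (1.0 - p) ** (n - j)
        pmf /= pmf.sum()
        k[idx] = rng.choice(j, size=idx.size, p=pmf)
    return k


def simulate_brightness_samples(
    scene: SceneParams,
    photo: PhotophysicsParams,
    n: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw n single-spot brightness values with ground-truth labels.

    Each sample: true size N ~ true_alpha, active count k ~ Binomial(N,
    maturation_p) conditioned on k >= 1 (dark complexes are never seen as
    spots), brightness = sum of k monomer draws. Returns columns
    ``brightness``, ``n_true``, ``k_active``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    alpha = np.asarray(scene.true_alpha, dtype=float)
    sizes = rng.choice(np.arange(1, alpha.size + 1), size=n, p=alpha / alpha.sum())
    k = _conditional_active_counts(sizes, photo.maturation_p, rng)
    draws = photo.draw_monomer_brightness(rng, int(k.sum()))
    idx = np.repeat(np.arange(n), k)
    brightness = np.zeros(n)
    np.add.at(brightness, idx, draws)
    return pd.DataFrame({"brightness": brightness, "n_true": sizes, "k_active": k})


def thinned_visible_pmf(alpha, f: float) -> np.ndarray:
    """Joint pmf P(N, k) of visible spots under independent thinning.

    Each subunit of a true N-mer is active with probability f; only spots with
    k >= 1 are visible. Entry [N-1, k-1] is the probability that a visible spot
    has true size N and k active fluorophores. This is the closed-form limit of
    complete subunit mixing at active-subunit fraction f.
    """
    alpha = np.asarray(alpha, dtype=float)
    if not (0.0 < f <= 1.0):
        raise ValueError("f must be in (0, 1]")
    nmax = alpha.size
    out = np.zeros((nmax, nmax))
    for n in range(1, nmax + 1):
        k = np.arange(1, n + 1)
        out[n - 1, : n] = alpha[n - 1] * special.comb(n, k) * f**k * (1 - f) ** (n - k)
    s = out.sum()
    if s <= 0:
        raise ValueError("no visible spots under the given alpha and f")
    return out / s


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------


def render_frame(
    positions: np.ndarray,
    intensities: np.ndarray,
    imaging: ImagingParams,
    field_size: tuple[float, float],
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render one camera frame from point emitters.

    Each emitter contributes an isotropic Gaussian PSF integrated over pixels
    (exact error-function pixel integration), with total flux equal to its
    intensity. Pixel values are Poisson(signal + background) * gain plus
    Gaussian read noise, clipped at zero; with ``rng=None`` the noiseless
    expectation (signal + background) * gain is returned.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        positions = positions.reshape(0, 2)
    intensities = np.asarray(intensities, dtype=float).ravel()
    if positions.shape[0] != intensities.size:
        raise ValueError("positions and intensities must have matching length")
    px = imaging.pixel_size
    shape = (int(round(field_size[1] / px)), int(round(field_size[0] / px)))
    signal = np.zeros(shape)
    sigma_px = imaging.psf_sigma_px
    half = int(math.ceil(4.0 * sigma_px)) + 1
    inv = 1.0 / (math.sqrt(2.0) * sigma_px)
    for (x, y), b in zip(positions, intensities):
        if b <= 0:
            continue
        cx, cy = x / px, y / px  # pixel units, pixel i covers [i, i+1)
        c0 = int(math.floor(cx)) - half
        c1 = int(math.floor(cx)) + half + 1
        r0 = int(math.floor(cy)) - half
        r1 = int(math.floor(cy)) + half + 1
        c0c, c1c = max(c0, 0), min(c1, shape[1])
        r0c, r1c = max(r0, 0), min(r1, shape[0])
        if c0c >= c1c or r0c >= r1c:
            continue
        cols = np.arange(c0c, c1c + 1)
        rows = np.arange(r0c, r1c + 1)
        ex = special.erf((cols - cx) * inv)
        ey = special.erf((rows - cy) * inv)
        gx = 0.5 * np.diff(ex)
        gy = 0.5 * np.diff(ey)
        signal[r0c:r1c, c0c:c1c] += b * np.outer(gy, gx)
    expected = signal + imaging.background_rate
    if rng is None:
        return expected * imaging.camera_gain
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    img = rng.poisson(expected).astype(float) * imaging.camera_gain
    if imaging.read_noise_sd > 0:
        img += rng.normal(0.0, imaging.read_noise_sd, shape)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# TOCCSL acquisitions
# ---------------------------------------------------------------------------


@dataclass
class ToccslRun:
    """One TOCCSL acquisition: labelled frames, timing, geometry, ground truth.

    ``truth`` maps frame name to the table of visible emitters rendered into it
    (absent for runs loaded from real data).
    """

    frames: dict[str, np.ndarray]
    timing: ProtocolTiming
    roi: Rect
    imaging: ImagingParams
    field_size: tuple[float, float]
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    FRAME_ORDER = ("pre_bleach", "post_bleach", "toccsl")

    def __post_init__(self) -> None:
        shapes = {f.shape for f in self.frames.values()}
        if len(shapes) > 1:
            raise ValueError("all frames in a run must share one shape")


def _render_population_frame(
    pop: OligomerPopulation,
    photo: PhotophysicsParams,
    imaging: ImagingParams,
    field_size,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    bright = pop.frame_brightness(photo, rng)
    vis = bright > 0
    frame = render_frame(
        np.column_stack([pop.x[vis], pop.y[vis]]), bright[vis], imaging, field_size, rng
    )
    return frame, pop.truth_table(bright)


def _acquire_run(
    pop: OligomerPopulation,
    scene: SceneParams,
    photo: PhotophysicsParams,
    imaging: ImagingParams,
    timing: ProtocolTiming,
    rng: np.random.Generator,
    n_bleach_substeps: int = 8,
) -> ToccslRun:
    """Run the pre-bleach/bleach/post-bleach/recovery sequence on a population."""
    D = scene.diffusion_coeff
    frames: dict[str, np.ndarray] = {}
    truth: dict[str, pd.DataFrame] = {}

    frames["pre_bleach"], truth["pre_bleach"] = _render_population_frame(
        pop, photo, imaging, scene.field_size, rng
    )
    pop.diffuse(timing.t_pre / 1000.0, D, rng)
    # the bleach pulse is long enough that molecules diffuse through the ROI
    # during it; subdivide so transiting molecules are bleached too
    sub_survival = photo.bleach_survival ** (1.0 / n_bleach_substeps)
    for _ in range(n_bleach_substeps):
        pop.bleach(timing.roi, sub_survival, rng)
        pop.diffuse(timing.t_bleach / 1000.0 / n_bleach_substeps, D, rng)
    pop.diffuse(timing.t_post / 1000.0, D, rng)
    frames["post_bleach"], truth["post_bleach"] = _render_population_frame(
        pop, photo, imaging, scene.field_size, rng
    )
    pop.diffuse((timing.t_recovery - timing.t_post) / 1000.0, D, rng)
    frames["toccsl"], truth["toccsl"] = _render_population_frame(
        pop, photo, imaging, scene.field_size, rng
    )
    return ToccslRun(
        frames=frames,
        timing=timing,
        roi=timing.roi,
        imaging=imaging,
        field_size=scene.field_size,
        truth=truth,
    )


def simulate_toccsl_run(
    scene: SceneParams,
    photo: PhotophysicsParams,
    imaging: ImagingParams,
    timing: ProtocolTiming,
    seed: int | np.random.Generator,
) -> ToccslRun:
    """Simulate one full TOCCSL acquisition with exact composition tracking."""
    timing.validate_roi(scene.field_rect)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = OligomerPopulation.sample(scene, photo, rng, pad=4.0 * imaging.psf_sigma)
    return _acquire_run(pop, scene, photo, imaging, timing, rng)


def exchange_subunits(pop: OligomerPopulation, n_events: int, rng: np.random.Generator) -> None:
    """Apply pairwise single-subunit swaps between random oligomer pairs.

    Each event picks two distinct oligomers and swaps one uniformly chosen
    subunit of each; the active/bleached identity travels with the subunit.
    Sizes and both global totals are conserved.
    """
    n = pop.n_oligomers
    if n < 2 or n_events <= 0:
        return
    i_idx = rng.integers(0, n, n_events)
    j_idx = rng.integers(0, n, n_events)
    j_idx = np.where(j_idx == i_idx, (j_idx + 1) % n, j_idx)
    u1 = rng.random(n_events)
    u2 = rng.random(n_events)
    size = pop.size
    act = pop.n_active
    for e in range(n_events):
        i = i_idx[e]
        j = j_idx[e]
        bit_i = 1 if u1[e] < act[i] / size[i] else 0
        bit_j = 1 if u2[e] < act[j] / size[j] else 0
        act[i] += bit_j - bit_i
        act[j] += bit_i - bit_j


def simulate_repetitive_series(
    scene: SceneParams,
    photo: PhotophysicsParams,
    imaging: ImagingParams,
    timing: ProtocolTiming,
    seed: int | np.random.Generator,
) -> list[ToccslRun]:
    """Simulate a repetitive TOCCSL series on one persistent population.

    Between consecutive runs the population diffuses for ``run_interval``
    seconds and undergoes Poisson(exchange_rate * run_interval * n_oligomers)
    subunit-swap events.
    """
    if timing.n_runs < 2:
        raise ValueError("a repetitive series requires n_runs >= 2")
    timing.validate_roi(scene.field_rect)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = OligomerPopulation.sample(scene, photo, rng, pad=4.0 * imaging.psf_sigma)
    runs = []
    for r in range(timing.n_runs):
        runs.append(_acquire_run(pop, scene, photo, imaging, timing, rng))
        if r < timing.n_runs - 1:
            n_ev = int(rng.poisson(scene.exchange_rate * timing.run_interval * pop.n_oligomers))
            exchange_subunits(pop, n_ev, rng)
            pop.diffuse(timing.run_interval, scene.diffusion_coeff, rng)
    return runs


def simulate_repetitive_brightness_series(
    true_alpha,
    photo: PhotophysicsParams,
    n_population: int,
    n_runs: int,
    run_interval: float,
    exchange_rate: float,
    seed: int | np.random.Generator,
    bleach_hit_prob: float = 0.066967,  # 1 - 0.5**(1/10): ~50% active after 10 runs
    spots_per_run: int = 750,
) -> tuple[list[pd.DataFrame], dict]:
    """Population-level repetitive TOCCSL: per-run spot-brightness tables.

    Abstracts away imaging: each run bleaches a random fraction
    ``bleach_hit_prob`` of oligomers completely (an oligomer is either inside
    the bleach region or not), then samples ``spots_per_run`` visible oligomers
    as the diffraction-limited spots of that run's recovery image. Between runs
    subunits exchange at ``exchange_rate`` (per oligomer per second).

    Returns per-run tables (brightness, n_true, k_active) and a summary with the
    terminal population state and active-subunit fraction ``f_active``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not (0.0 < bleach_hit_prob < 1.0):
        raise ValueError("bleach_hit_prob must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = np.asarray(true_alpha, dtype=float)
    if np.any(alpha < 0) or abs(alpha.sum() - 1.0) > 1e-12:
        raise ValueError("true_alpha must be a probability vector")
    size = rng.choice(np.arange(1, alpha.size + 1), size=n_population, p=alpha).astype(np.int64)
    act = rng.binomial(size, photo.maturation_p).astype(np.int64)
    pop = OligomerPopulation(
        x=np.zeros(n_population), y=np.zeros(n_population), size=size, n_active=act,
        mobile=np.ones(n_population, dtype=bool), bounds=Rect(0, 0, 1, 1),
    )
    tables = []
    f_per_run = []
    for r in range(n_runs):
        hit = rng.random(n_population) < bleach_hit_prob
        pop.n_active[hit] = 0
        # active-subunit fraction of the population the run's spots sample from
        # (oligomers outside the bleach region, i.e. not hit this run)
        f_per_run.append(
            float(pop.n_active[~hit].sum() / max(pop.size[~hit].sum(), 1))
        )
        vis = np.flatnonzero(pop.n_active >= 1)
        take = min(spots_per_run, vis.size)
        sel = rng.choice(vis, size=take, replace=False)
        k = pop.n_active[sel]
        draws = photo.draw_monomer_brightness(rng, int(k.sum()))
        bright = np.zeros(take)
        np.add.at(bright, np.repeat(np.arange(take), k), draws)
        tables.append(
            pd.DataFrame({"brightness": bright, "n_true": pop.size[sel], "k_active": k})
        )
        if r < n_runs - 1:
            n_ev = int(rng.poisson(exchange_rate * run_interval * n_population))
            exchange_subunits(pop, n_ev, rng)
    summary = {
        "size": pop.size.copy(),
        "n_active": pop.n_active.copy(),
        "f_active": float(pop.n_active.sum() / pop.size.sum()),
        "f_per_run": np.asarray(f_per_run),
    }
    return tables, summary


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryCurve:
    """Pre-bleach-normalized FRAP recovery, I(0) expected 0."""

    times: np.ndarray
    normalized_intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.normalized_intensity, dtype=float)
        if t.ndim != 1 or t.size != i.size:
            raise ValueError("times and intensities must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(i)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "normalized_intensity", i)


def simulate_frap_curve(
    mobile_fraction: float,
    recovery_rate: float,
    noise_sd: float,
    timepoints,
    seed: int | np.random.Generator,
) -> RecoveryCurve:
    """Single-exponential saturating recovery with additive Gaussian noise."""
    if not (0.0 <= mobile_fraction <= 1.0):
        raise ValueError("mobile_fraction must be in [0, 1]")
    if recovery_rate < 0:
        raise ValueError("recovery_rate must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(timepoints, dtype=float)
    clean = mobile_fraction * (1.0 - np.exp(-recovery_rate * t))
    return RecoveryCurve(times=t, normalized_intensity=clean + rng.normal(0, noise_sd, t.size))


# ---------------------------------------------------------------------------
# monomer calibration fixtures
# ---------------------------------------------------------------------------


def simulate_monomer_calibration_frames(
    photo: PhotophysicsParams,
    imaging: ImagingParams,
    field_size: tuple[float, float],
    density: float,
    n_frames: int,
    seed: int | np.random.Generator,
) -> list[np.ndarray]:
    """Sparse single-fluorophore frames, as after extensive photobleaching.

    Emulates the monomer-brightness calibration condition: so few active
    fluorophores remain that every spot carries exactly one.
    """
    if density <= 0 or n_frames < 1:
        raise ValueError("density must be > 0 and n_frames >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pad = 4.0 * imaging.psf_sigma
    area = (field_size[0] + 2 * pad) * (field_size[1] + 2 * pad)
    frames = []
    for _ in range(n_frames):
        n = int(rng.poisson(density * area))
        pos = np.column_stack(
            [
                rng.uniform(-pad, field_size[0] + pad, n),
                rng.uniform(-pad, field_size[1] + pad, n),
            ]
        )
        b = photo.draw_monomer_brightness(rng, n)
        frames.append(render_frame(pos, b, imaging, field_size, rng))
    return frames
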