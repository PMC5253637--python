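"""Ground-truth validation experiments for the whole pipeline.

Every function simulates data with the synthetic module at documented study
conditions, runs the corresponding analysis, and returns measured performance.
They are shared by the test suite and by ``scripts/acceptance.py``; problem
sizes are part of each function's contract (see docs/methods.md).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from scipy.stats import lognorm

from .mixture import (
    BrightnessPDF,
    GRID_SIZE,
    MixtureModel,
    autoconvolve_pdf,
    binomial_visible_mixture,
    correct_maturation,
    estimate_monomer_pdf,
)
from .params import ImagingParams, PhotophysicsParams, ProtocolTiming, Rect, SceneParams
from .protocol import (
    AnalysisSettings,
    analyze_repetitive_series,
    extract_roi_spots,
)
from .quantify import fit_mobile_fraction, measure_frame_density
from .spots import analyze_frame
from .synthetic import (
    simulate_brightness_samples,
    simulate_frap_curve,
    simulate_monomer_calibration_frames,
    simulate_repetitive_brightness_series,
    simulate_toccsl_run,
    thinned_visible_pmf,
    render_frame,
)

__all__ = [
    "autoconvolution_ks",
    "mixture_recovery",
    "maturation_roundtrip",
    "toccsl_imaging_benchmark",
    "repetitive_discrimination",
    "frap_benchmark",
    "density_benchmark",
]

# benchmark study conditions: the oligomer mixture used for end-to-end checks
# (mean size 1.8, heterogeneous monomer-to-tetramer population)
BENCH_ALPHA = (0.45, 0.35, 0.15, 0.05)
MIX_ALPHA_5 = (0.35, 0.30, 0.20, 0.10, 0.05)


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def analytic_monomer_pdf(
    photo: PhotophysicsParams, grid_max: float = 1300.0, grid_size: int = GRID_SIZE
) -> BrightnessPDF:
    """The exact lognormal monomer pdf on a grid (no sampling, no smoothing)."""
    mu, sig = photo.lognormal_params
    grid = np.linspace(0.0, grid_max, grid_size)
    dens = lognorm.pdf(grid, sig, scale=np.exp(mu))
    dens /= np.trapezoid(dens, grid)
    return BrightnessPDF(grid=grid, density=dens, label="rho_1")


def autoconvolution_ks(
    seed: int, n_draws: int = 1_000_000, orders=(2, 3, 4, 5)
) -> dict[int, float]:
    """KS distance of each rho_N against Monte-Carlo N-fold sums of rho_1.

    rho_1 is the analytic lognormal monomer law (mean 100 counts, CV 0.3); the
    Monte-Carlo oracle draws ``n_draws`` independent N-fold sums per order.
    """
    rng = _rng(seed)
    photo = PhotophysicsParams()
    mu, sig = photo.lognormal_params
    rho1 = analytic_monomer_pdf(photo)
    out = {}
    for n in orders:
        rn = autoconvolve_pdf(rho1, n)
        cdf = np.concatenate(
            [[0.0], np.cumsum(0.5 * (rn.density[1:] + rn.density[:-1]) * rn.dx)]
        )
        draws = np.sort(rng.lognormal(mu, sig, (n_draws, n)).sum(axis=1))
        model_cdf = np.interp(draws, rn.grid, cdf)
        ecdf = np.arange(1, n_draws + 1) / n_draws
        out[n] = float(np.max(np.abs(model_cdf - ecdf)))
    return out


def mixture_recovery(
    seed: int,
    n_datasets: int = 100,
    n_samples: int = 750,
    alpha=MIX_ALPHA_5,
    n_calibration: int = 1000,
) -> dict:
    """Bias and RMSE of fitted oligomer fractions at the standard sample size.

    Each dataset draws a fresh monomer calibration and ``n_samples`` mixture
    spots (full maturation), then fits. Returns per-component bias and RMSE
    plus simplex-constraint checks.
    """
    alpha = np.asarray(alpha, dtype=float)
    scene = SceneParams(true_alpha=tuple(alpha))
    photo = PhotophysicsParams()
    fitted = np.empty((n_datasets, alpha.size))
    simplex_ok = True
    rng = _rng(seed)
    for i in range(n_datasets):
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
        cal = photo.draw_monomer_brightness(sub, n_calibration)
        rho1 = estimate_monomer_pdf(cal, n_max=alpha.size)
        samples = simulate_brightness_samples(scene, photo, n_samples, sub)
        d = MixtureModel(rho1, alpha.size).fit(samples["brightness"].to_numpy())
        fitted[i] = d.alpha
        simplex_ok &= bool(abs(d.alpha.sum() - 1.0) < 1e-9 and np.all(d.alpha >= 0))
    bias = fitted.mean(axis=0) - alpha
    rmse = np.sqrt(((fitted - alpha) ** 2).mean(axis=0))
    return {"bias": bias, "rmse": rmse, "simplex_ok": simplex_ok, "fitted": fitted}


def maturation_roundtrip(seed: int, ps=(0.6, 0.8, 0.95), reps: int = 200,
                         n_max: int = 5) -> float:
    """Worst-case |alpha - recovered| over random simplex vectors and p values."""
    rng = _rng(seed)
    worst = 0.0
    for p in ps:
        for _ in range(reps):
            alpha = rng.dirichlet(np.ones(n_max))
            observed = binomial_visible_mixture(alpha, p)
            recovered = correct_maturation(observed, p)
            worst = max(worst, float(np.abs(recovered - alpha).max()))
    return worst


def toccsl_imaging_benchmark(
    seed: int,
    min_pooled_spots: int = 750,
    max_cells: int = 150,
    alpha=BENCH_ALPHA,
) -> dict:
    """End-to-end imaging pipeline: simulate, detect, fit, pool, invert.

    Study conditions: surface density 0.35 oligomers/um^2 (sparse enough that
    recovery entrants are resolvable single spots, as the protocol requires),
    D = 0.5 um^2/s, 80% mobile, 10x10 um bleach ROI in a 20x20 um field,
    6 s recovery; monomer calibration from sparse single-fluorophore frames
    analysed with the same spot pipeline. Cells are pooled until
    ``min_pooled_spots`` accepted in-ROI spots are reached.

    Returns recovered mean oligomer size (truth = mean of ``alpha``) and the
    relative bias of fitted spot brightness against matched ground truth.
    """
    rng = _rng(seed)
    photo = PhotophysicsParams()
    imaging = ImagingParams()
    scene = SceneParams(true_alpha=tuple(alpha), density=0.35, diffusion_coeff=0.5,
                        mobile_fraction=0.8, field_size=(20.0, 20.0))
    timing = ProtocolTiming(roi=Rect(5.0, 5.0, 15.0, 15.0), t_recovery=6000.0)
    settings = AnalysisSettings()

    frames = simulate_monomer_calibration_frames(
        photo, imaging, scene.field_size, 0.05, 30, rng
    )
    cal = np.concatenate([
        analyze_frame(f, imaging.psf_sigma_px, imaging.pixel_size,
                      settings.detection_threshold, settings.criteria)[0]["brightness"]
        .to_numpy()
        for f in frames
    ])
    rho1 = estimate_monomer_pdf(cal, n_max=len(alpha))

    pooled: list[np.ndarray] = []
    fit_errors: list[float] = []
    truth_b: list[float] = []
    cells = 0
    while sum(b.size for b in pooled) < min_pooled_spots and cells < max_cells:
        run = simulate_toccsl_run(scene, photo, imaging, timing, rng)
        table, _ = extract_roi_spots(run, settings)
        pooled.append(table["brightness"].to_numpy() if len(table) else np.empty(0))
        cells += 1
        # match accepted spots to ground-truth emitters for the brightness bias
        truth = run.truth["toccsl"]
        if len(table) and len(truth):
            tree = cKDTree(np.column_stack([truth["x"], truth["y"]]))
            dist, idx = tree.query(np.column_stack([table["x"], table["y"]]))
            close = dist < 2.0 * imaging.psf_sigma
            fit_errors.extend(
                (table["brightness"].to_numpy()[close]
                 - truth["brightness"].to_numpy()[idx[close]]).tolist()
            )
            truth_b.extend(truth["brightness"].to_numpy()[idx[close]].tolist())
    brightness = np.concatenate(pooled)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dist_fit = MixtureModel(rho1, len(alpha)).fit(brightness)
    true_mean = float(np.sum(np.arange(1, len(alpha) + 1) * np.asarray(alpha)))
    return {
        "mean_size": dist_fit.mean_size,
        "true_mean_size": true_mean,
        "alpha": dist_fit.alpha,
        "n_spots": brightness.size,
        "n_cells": cells,
        "brightness_bias": float(np.mean(fit_errors) / np.mean(truth_b)),
    }


def repetitive_discrimination(
    seed: int,
    n_series: int = 50,
    n_runs: int = 10,
    n_population: int = 4000,
    spots_per_run: int = 750,
    fast_exchange_rate: float = 0.1,
    alpha=BENCH_ALPHA,
) -> dict:
    """Stable-vs-exchanging verdict accuracy over seeded repetitive series.

    ``n_series`` kinetically trapped series (exchange rate 0) and ``n_series``
    fast-exchange series are simulated (one run per minute, as in the
    repetitive protocol) and classified. Also pools the terminal-run
    ground-truth (N, k) labels of the fast-exchange series and tests them
    against the closed-form Binomial(N, f | k >= 1) mixing limit by chi-square.
    """
    photo = PhotophysicsParams()
    rng = _rng(seed)
    cal = photo.draw_monomer_brightness(rng, 1000)
    rho1 = estimate_monomer_pdf(cal, n_max=len(alpha))
    settings = AnalysisSettings(n_max=len(alpha), seed=int(rng.integers(0, 2**31 - 1)))

    nmax = len(alpha)
    correct = {"stable": 0, "exchanging": 0}
    obs = np.zeros((nmax, nmax))
    expected = np.zeros((nmax, nmax))
    for label, k_ex in (("stable", 0.0), ("exchanging", fast_exchange_rate)):
        for _ in range(n_series):
            tables, summary = simulate_repetitive_brightness_series(
                alpha, photo, n_population, n_runs, 60.0, k_ex,
                rng, spots_per_run=spots_per_run,
            )
            result = analyze_repetitive_series(
                [t["brightness"].to_numpy() for t in tables], rho1, settings
            )
            if result.verdict == label:
                correct[label] += 1
            if label == "exchanging":
                last = tables[-1]
                for n_true, k in zip(last["n_true"], last["k_active"]):
                    obs[n_true - 1, k - 1] += 1
                expected += thinned_visible_pmf(
                    alpha, summary["f_per_run"][-1]
                ) * len(last)
    mask = expected > 5
    chi2 = float(((obs[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    dof = int(mask.sum() - 1)
    pvalue = float(stats.chi2.sf(chi2, dof))
    return {
        "accuracy_stable": correct["stable"] / n_series,
        "accuracy_exchanging": correct["exchanging"] / n_series,
        "accuracy": (correct["stable"] + correct["exchanging"]) / (2 * n_series),
        "chi2": chi2,
        "chi2_dof": dof,
        "chi2_pvalue": pvalue,
    }


def frap_benchmark(
    seed: int, mobile_fraction: float = 0.8, n_curves: int = 100,
    noise_sd: float = 0.02, recovery_rate: float = 0.2,
) -> dict:
    """Mobile-fraction estimator performance on noisy synthetic curves."""
    rng = _rng(seed)
    t = np.arange(0.0, 30.0, 0.5)
    est = np.array([
        fit_mobile_fraction(
            simulate_frap_curve(mobile_fraction, recovery_rate, noise_sd, t, rng)
        ).mobile_fraction
        for _ in range(n_curves)
    ])
    return {"mean": float(est.mean()), "sd": float(est.std(ddof=1)), "estimates": est}


def density_benchmark(
    seed: int, densities=(25.0, 100.0, 400.0, 800.0), field: float = 8.0
) -> dict:
    """Surface-density estimates from rendered frames across the density range.

    Monomeric emitters at known density are rendered (with a padded source
    region so border flux is unbiased) and the mean-intensity estimator is
    compared with truth; returns relative errors and the linearity R^2.
    """
    rng = _rng(seed)
    photo = PhotophysicsParams()
    imaging = ImagingParams()
    pad = 4.0 * imaging.psf_sigma
    estimates = []
    for dens in densities:
        n = rng.poisson(dens * (field + 2 * pad) ** 2)
        pos = np.column_stack([
            rng.uniform(-pad, field + pad, n), rng.uniform(-pad, field + pad, n)
        ])
        b = photo.draw_monomer_brightness(rng, n)
        frame = render_frame(pos, b, imaging, (field, field), rng)
        est = measure_frame_density(frame, imaging, photo.monomer_mean_brightness)
        estimates.append(est.density)
    estimates = np.asarray(estimates)
    densities = np.asarray(densities, dtype=float)
    rel_err = estimates / densities - 1.0
    slope, intercept = np.polyfit(densities, estimates, 1)
    r2 = 1.0 - np.sum((estimates - (slope * densities + intercept)) ** 2) / np.sum(
        (estimates - estimates.mean()) ** 2
    )
    return {"estimates": estimates, "rel_err": rel_err, "r2": float(r2)}
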