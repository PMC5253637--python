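"""TOCCSL protocol analysis: bleach gate, run stoichiometry, repetitive series.

Workflow per acquisition: verify that the bleach pulse removed essentially all
fluorescence inside the bleach region (post-bleach check); detect, fit and
filter single-molecule spots inside the region on the recovery (TOCCSL) frame;
fit their brightness pdf against a monomer calibration to obtain oligomer
fractions; estimate the surface density from the pre-bleach frame. A
repetitive series (one run per minute on the same region) is summarized by the
trend of the mean oligomer size over run index: stable complexes keep the
brightness distribution unchanged while subunit exchange mixes bleached
protomers into visible complexes and shifts the distribution towards smaller
sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mixture import BrightnessPDF, MixtureModel, OligomerDistribution
from .params import ImagingParams, Rect
from .quantify import DensityEstimate, surface_density
from .spots import FilterCriteria, analyze_frame, bandpass
from .synthetic import ToccslRun

__all__ = [
    "AnalysisSettings",
    "BleachCheck",
    "ToccslRunResult",
    "RunSeriesResult",
    "CompletenessError",
    "check_bleach_completeness",
    "extract_roi_spots",
    "extract_roi_brightness",
    "analyze_toccsl_run",
    "analyze_toccsl_pooled",
    "analyze_repetitive_series",
]


class CompletenessError(RuntimeError):
    """The post-bleach check failed: residual fluorescence inside the ROI."""


@dataclass(frozen=True)
class AnalysisSettings:
    """Tunables of the image-analysis and verdict stages."""

    detection_threshold: float = 4.0
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    n_max: int = 5
    bootstrap_reps: int = 100
    bootstrap_frac: float = 0.5
    bootstrap_divisor: float = float(np.sqrt(2.0))
    completeness_threshold: float = 0.05
    min_spots_per_run: int = 50
    significance: float = 0.05
    area_fraction: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class BleachCheck:
    metric: float
    passed: bool
    vacuous: bool = False


@dataclass(frozen=True)
class ToccslRunResult:
    distribution: OligomerDistribution | None
    density: DensityEstimate | None
    completeness: BleachCheck
    brightness: np.ndarray
    filter_log: dict
    flags: frozenset


@dataclass(frozen=True)
class RunSeriesResult:
    """Repetitive-TOCCSL summary: per-run fractions and exchange verdict."""

    distributions: list[OligomerDistribution]
    run_times: np.ndarray  # minutes from first bleach
    mean_sizes: np.ndarray
    mean_size_se: np.ndarray
    trend_slope: float
    trend_slope_se: float
    trend_pvalue_one_sided: float
    detectable_slope: float  # smallest |slope| the series could have flagged
    verdict: str  # stable | exchanging | inconclusive


def _roi_noise_sd(frame: np.ndarray, region: Rect, imaging: ImagingParams) -> float:
    """Band-passed noise sd inside a structure-poor region (negative-side MAD)."""
    sub = bandpass(frame, imaging.psf_sigma_px)[region.to_pixels(imaging.pixel_size, frame.shape)]
    med = np.median(sub)
    neg = med - sub[sub < med]
    return 1.4826 * float(np.median(neg)) if neg.size else float(sub.std())


def _structure_energy(frame: np.ndarray, roi_px, psf_sigma_px: float) -> tuple[float, float]:
    """Positive band-pass energy inside a region plus its noise floor."""
    sub = bandpass(frame, psf_sigma_px)[roi_px]
    med = np.median(sub)
    mad_sd = 1.4826 * float(np.median(np.abs(sub - med)))
    energy = float(np.clip(sub, 0.0, None).sum())
    # expected positive-part sum of pure zero-mean Gaussian noise
    floor = sub.size * mad_sd / np.sqrt(2.0 * np.pi)
    return energy, floor


def check_bleach_completeness(
    run_or_frames,
    roi: Rect | None = None,
    imaging: ImagingParams | None = None,
    threshold: float = 0.05,
) -> BleachCheck:
    """Fraction of pre-bleach spot structure remaining inside the ROI post-bleach.

    Accepts a :class:`~toccsl.synthetic.ToccslRun` or a (pre_bleach,
    post_bleach) frame pair with explicit roi/imaging. The metric compares the
    noise-corrected positive band-pass energy inside the ROI after the bleach
    pulse with the one before it; the run passes when the ratio is below
    ``threshold``. An ROI devoid of structure already before bleaching passes
    vacuously with a warning.
    """
    if isinstance(run_or_frames, ToccslRun):
        run = run_or_frames
        pre, post = run.frames["pre_bleach"], run.frames.get("post_bleach")
        roi = run.roi
        imaging = run.imaging
    else:
        pre, post = run_or_frames
    if post is None:
        raise ValueError("post-bleach frame is required for the completeness check")
    if roi is None or imaging is None:
        raise ValueError("roi and imaging must be given with raw frames")
    roi_px = roi.to_pixels(imaging.pixel_size, pre.shape)
    e_pre, f_pre = _structure_energy(pre, roi_px, imaging.psf_sigma_px)
    e_post, f_post = _structure_energy(post, roi_px, imaging.psf_sigma_px)
    denom = e_pre - f_pre
    if denom <= 0:
        warnings.warn("no emitter structure inside the ROI before bleaching; "
                      "completeness check is vacuous", UserWarning)
        return BleachCheck(metric=0.0, passed=True, vacuous=True)
    metric = max(0.0, e_post - f_post) / denom
    return BleachCheck(metric=float(metric), passed=bool(metric < threshold))


def extract_roi_spots(run: ToccslRun, settings: AnalysisSettings):
    """Accepted single-spot fits inside the ROI of the TOCCSL frame.

    Detection and fitting run on a crop of the recovery frame (ROI plus a
    fit-window margin) — only spots that re-entered the bleached region are
    isolated single molecules; the unbleached surround stays dense.
    """
    frame = run.frames["toccsl"]
    px = run.imaging.pixel_size
    margin = (int(np.ceil(4.0 * run.imaging.psf_sigma_px)) + 2) * px
    crop_rect = Rect(
        max(0.0, run.roi.x0 - margin),
        max(0.0, run.roi.y0 - margin),
        min(run.field_size[0], run.roi.x1 + margin),
        min(run.field_size[1], run.roi.y1 + margin),
    )
    rows, cols = crop_rect.to_pixels(px, frame.shape)
    crop = frame[rows, cols]
    # noise level from the central half of the bleached region: mostly empty at
    # the recovery onset, unlike the dense unbleached surround in the margin
    cx, cy = 0.5 * (run.roi.x0 + run.roi.x1), 0.5 * (run.roi.y0 + run.roi.y1)
    center = Rect(cx - run.roi.width / 4, cy - run.roi.height / 4,
                  cx + run.roi.width / 4, cy + run.roi.height / 4)
    noise_sd = _roi_noise_sd(frame, center, run.imaging)
    table, log = analyze_frame(
        crop,
        run.imaging.psf_sigma_px,
        px,
        settings.detection_threshold,
        settings.criteria,
        noise_sd=noise_sd,
    )
    if len(table):
        table = table.assign(x=table["x"] + cols.start * px, y=table["y"] + rows.start * px)
        inside = run.roi.contains(table["x"].to_numpy(), table["y"].to_numpy())
        table = table[inside]
    log = dict(log, in_roi=len(table))
    return table, log


def extract_roi_brightness(
    run: ToccslRun, settings: AnalysisSettings
) -> tuple[np.ndarray, dict]:
    """Accepted single-spot brightness values inside the ROI (see extract_roi_spots)."""
    table, log = extract_roi_spots(run, settings)
    return table["brightness"].to_numpy() if len(table) else np.empty(0), log


def _prebleach_density(run: ToccslRun, rho1: BrightnessPDF, area_fraction: float) -> DensityEstimate:
    """Surface density from the pre-bleach frame via mean intensity / B_1."""
    imaging = run.imaging
    frame = run.frames["pre_bleach"]
    margin = int(np.ceil(4.0 * imaging.psf_sigma_px))
    interior = frame[margin:-margin, margin:-margin]
    per_px = float(interior.mean()) - imaging.background_rate * imaging.camera_gain
    per_area = max(per_px, 0.0) / imaging.pixel_size**2
    return surface_density(per_area, rho1.mean, area_fraction)


def analyze_toccsl_run(
    run: ToccslRun,
    rho1: BrightnessPDF,
    settings: AnalysisSettings | None = None,
) -> ToccslRunResult:
    """Full single-run analysis: completeness gate, ROI stoichiometry, density.

    Raises :class:`CompletenessError` when the post-bleach check fails — no
    stoichiometry is ever reported from an incompletely bleached run. A run
    with fewer accepted spots than ``min_spots_per_run`` is returned flagged
    ("insufficient_spots") with the spot brightness table so it can be pooled
    with other cells rather than silently dropped.
    """
    settings = settings or AnalysisSettings()
    check = check_bleach_completeness(run, threshold=settings.completeness_threshold)
    if not check.passed:
        raise CompletenessError(
            f"post-bleach residual structure {check.metric:.3f} exceeds "
            f"threshold {settings.completeness_threshold}"
        )
    brightness, log = extract_roi_brightness(run, settings)
    flags = set()
    distribution = None
    if brightness.size < settings.min_spots_per_run:
        flags.add("insufficient_spots")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            distribution = MixtureModel(rho1, settings.n_max).fit(brightness)
        if distribution.undersampled:
            flags.add("undersampled")
    density = _prebleach_density(run, rho1, settings.area_fraction)
    return ToccslRunResult(
        distribution=distribution,
        density=density,
        completeness=check,
        brightness=brightness,
        filter_log=log,
        flags=frozenset(flags),
    )


def analyze_toccsl_pooled(
    runs: list[ToccslRun],
    rho1: BrightnessPDF,
    settings: AnalysisSettings | None = None,
) -> tuple[OligomerDistribution, np.ndarray]:
    """Pool accepted ROI spots from many cells and fit one oligomer distribution.

    Pooling across cells is the standard way to reach the recommended 750-spot
    sample size. Runs failing the completeness gate raise; pooling is
    order-invariant.
    """
    settings = settings or AnalysisSettings()
    pooled = []
    for run in runs:
        check = check_bleach_completeness(run, threshold=settings.completeness_threshold)
        if not check.passed:
            raise CompletenessError("a pooled run failed the post-bleach check")
        b, _ = extract_roi_brightness(run, settings)
        pooled.append(b)
    brightness = np.concatenate(pooled) if pooled else np.empty(0)
    dist = MixtureModel(rho1, settings.n_max).fit(brightness)
    return dist, brightness


def analyze_repetitive_series(
    series,
    rho1: BrightnessPDF,
    settings: AnalysisSettings | None = None,
    run_times_min: np.ndarray | None = None,
) -> RunSeriesResult:
    """Exchange-vs-stable verdict from a repetitive TOCCSL series.

    ``series`` is a list over run index of pooled spot-brightness arrays (one
    per run; pool cells before calling, or pass a list of lists of
    :class:`ToccslRun` per cell, which is pooled per run index here). Per-run
    mean oligomer sizes, weighted by half-sample-bootstrap errors, are
    regressed on run time; the verdict is "exchanging" when the slope is
    negative and one-sidedly significant at ``settings.significance``, "stable"
    when the trend is indistinguishable from zero, and "inconclusive" when any
    run is too poorly sampled to trust.
    """
    settings = settings or AnalysisSettings()
    if len(series) and isinstance(series[0], (list, tuple)):
        # cells x runs of ToccslRun -> pooled brightness per run index
        n_runs = len(series[0])
        pooled = []
        for r in range(n_runs):
            per_run = []
            for cell in series:
                check = check_bleach_completeness(cell[r],
                                                  threshold=settings.completeness_threshold)
                if not check.passed:
                    warnings.warn("excluding a run that failed the post-bleach check",
                                  UserWarning)
                    continue
                b, _ = extract_roi_brightness(cell[r], settings)
                per_run.append(b)
            pooled.append(np.concatenate(per_run) if per_run else np.empty(0))
        series = pooled
    series = [np.asarray(b, dtype=float).ravel() for b in series]
    if len(series) < 3:
        raise ValueError("a repetitive series needs at least 3 runs")
    if run_times_min is None:
        run_times_min = np.arange(len(series), dtype=float)
    model = MixtureModel(rho1, settings.n_max)
    rng = np.random.default_rng(settings.seed)
    dists = []
    mean_sizes = []
    ses = []
    low_sampled = 0
    for b in series:
        if b.size < settings.min_spots_per_run:
            low_sampled += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = model.fit(b)
        dists.append(d)
        mean_sizes.append(d.mean_size)
        m = max(2, int(round(settings.bootstrap_frac * b.size)))
        sizes = np.empty(settings.bootstrap_reps)
        for rep in range(settings.bootstrap_reps):
            sub = rng.choice(b, size=m, replace=False)
            sizes[rep] = model.fit(sub, warn_undersampled=False).mean_size
        ses.append(max(sizes.std(ddof=1) / settings.bootstrap_divisor, 1e-6))
    mean_sizes = np.asarray(mean_sizes)
    ses = np.asarray(ses)
    X = sm.add_constant(np.asarray(run_times_min, dtype=float))
    fit = sm.WLS(mean_sizes, X, weights=1.0 / ses**2).fit()
    slope = float(fit.params[1])
    slope_se = float(fit.bse[1])
    p_two = float(fit.pvalues[1])
    p_one = p_two / 2.0 if slope < 0 else 1.0 - p_two / 2.0
    from scipy import stats as sp_stats

    t_crit = sp_stats.t.ppf(1.0 - settings.significance, df=len(series) - 2)
    detectable = float(t_crit * slope_se)
    if low_sampled > len(series) // 2:
        verdict = "inconclusive"
    elif slope < 0 and p_one < settings.significance:
        verdict = "exchanging"
    else:
        verdict = "stable"
    return RunSeriesResult(
        distributions=dists,
        run_times=np.asarray(run_times_min, dtype=float),
        mean_sizes=mean_sizes,
        mean_size_se=ses,
        trend_slope=slope,
        trend_slope_se=slope_se,
        trend_pvalue_one_sided=float(p_one),
        detectable_slope=detectable,
        verdict=verdict,
    )
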