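"""Tests of spot detection, Gaussian fitting and selection filters."""

import numpy as np
import pytest

from toccsl.params import ImagingParams, PhotophysicsParams
from toccsl.spots import (
    FilterCriteria,
    SpotFit,
    detect_spots,
    filter_spots,
    fit_gaussian_spot,
)
from toccsl.synthetic import render_frame


def _make_fit(x, y, sigma=0.2, b=100.0, quality=0.9, flags=()):
    return SpotFit(x=x, y=y, sigma=sigma, brightness_B=b, background=5.0,
                   fit_quality=quality, flags=frozenset(flags))


class TestDetection:
    def test_blank_frames_rare_false_positives(self, imaging):
        # 5-sigma threshold: fewer than one false maximum per 1e4 pixels
        n_px = 0
        n_fp = 0
        for seed in range(15):
            frame = render_frame(np.empty((0, 2)), np.empty(0), imaging, (16.0, 16.0),
                                 np.random.default_rng(seed))
            n_fp += len(detect_spots(frame, 5.0, imaging.psf_sigma_px))
            n_px += frame.size
        assert n_fp / n_px < 1e-4

    def test_single_emitter_found_within_one_pixel(self, imaging):
        rng = np.random.default_rng(21)
        for _ in range(60):
            x, y = rng.uniform(1.2, 2.8, 2)
            frame = render_frame(np.array([[x, y]]), np.array([300.0]), imaging,
                                 (4.0, 4.0), rng)
            peaks = detect_spots(frame, 5.0, imaging.psf_sigma_px)
            assert len(peaks) == 1
            r, c = peaks[0]
            assert abs(c + 0.5 - x / imaging.pixel_size) <= 1.0
            assert abs(r + 0.5 - y / imaging.pixel_size) <= 1.0

    def test_resolved_pair_detected_as_two(self, imaging):
        d = 5 * imaging.psf_sigma
        pos = np.array([[2.0, 2.0], [2.0 + d, 2.0]])
        frame = render_frame(pos, np.array([200.0, 200.0]), imaging, (5.0, 5.0),
                             np.random.default_rng(0))
        assert len(detect_spots(frame, 5.0, imaging.psf_sigma_px)) == 2

    def test_input_validation(self):
        with pytest.raises(ValueError, match="psf_sigma"):
            detect_spots(np.zeros((5, 5)), 5.0, 0.0)
        with pytest.raises(ValueError, match="finite"):
            detect_spots(np.full((5, 5), np.nan), 5.0, 1.0)


class TestGaussianFit:
    def test_noiseless_round_trip(self, imaging):
        im = ImagingParams(background_rate=3.0, read_noise_sd=0.0)
        frame = render_frame(np.array([[2.03, 1.96]]), np.array([100.0]), im,
                            (4.0, 4.0), rng=None)
        peak = detect_spots(frame, 5.0, im.psf_sigma_px)[0]
        fit = fit_gaussian_spot(frame, peak, im.psf_sigma_px, im.pixel_size)
        assert not fit.flags
        assert fit.brightness_B == pytest.approx(100.0, rel=0.01)
        assert fit.x == pytest.approx(2.03, abs=0.01)
        assert fit.y == pytest.approx(1.96, abs=0.01)
        assert fit.background == pytest.approx(3.0, abs=0.05)

    def test_flat_image_flagged_failed(self, imaging):
        fit = fit_gaussian_spot(np.full((25, 25), 7.0), (12, 12), imaging.psf_sigma_px)
        assert "failed" in fit.flags

    def test_border_spot_flagged_edge(self, imaging):
        frame = np.zeros((30, 30))
        fit = fit_gaussian_spot(frame, (2, 15), imaging.psf_sigma_px)
        assert "edge" in fit.flags

    def test_localization_precision_at_good_snr(self, imaging):
        # RMSE below psf_sigma / 2 for SNR >= 5
        rng = np.random.default_rng(31)
        errs = []
        for _ in range(150):
            x, y = rng.uniform(1.5, 2.5, 2)
            frame = render_frame(np.array([[x, y]]), np.array([150.0]), imaging,
                                 (4.0, 4.0), rng)
            peaks = detect_spots(frame, 4.0, imaging.psf_sigma_px)
            if len(peaks) != 1:
                continue
            f = fit_gaussian_spot(frame, peaks[0], imaging.psf_sigma_px, imaging.pixel_size)
            if f.flags:
                continue
            errs.append((f.x - x) ** 2 + (f.y - y) ** 2)
        assert np.sqrt(np.mean(errs)) < imaging.psf_sigma / 2

    def test_brightness_unbiased_over_many_monomers(self, imaging):
        # mean fitted brightness within 3 s.e. of the generating mean
        photo = PhotophysicsParams()
        rng = np.random.default_rng(41)
        fitted = []
        truth = []
        for _ in range(1200):
            x, y = rng.uniform(1.5, 2.5, 2)
            b = photo.draw_monomer_brightness(rng, 1)
            frame = render_frame(np.array([[x, y]]), b, imaging, (4.0, 4.0), rng)
            peaks = detect_spots(frame, 4.0, imaging.psf_sigma_px)
            if len(peaks) != 1:
                continue
            f = fit_gaussian_spot(frame, peaks[0], imaging.psf_sigma_px, imaging.pixel_size)
            if f.flags:
                continue
            fitted.append(f.brightness_B)
            truth.append(b[0])
        diff = np.asarray(fitted) - np.asarray(truth)
        se = diff.std(ddof=1) / np.sqrt(diff.size)
        assert diff.size > 850
        assert abs(diff.mean()) < 3 * se


class TestFilters:
    def test_overlapping_pair_both_removed(self):
        sig = 0.2
        fits = [_make_fit(1.0, 1.0), _make_fit(1.0 + sig, 1.0), _make_fit(3.0, 3.0)]
        kept, log = filter_spots(fits, FilterCriteria(), psf_sigma=sig)
        assert log["overlap"] == 2
        assert [f.x for f in kept] == [3.0]

    def test_clean_spots_pass_unchanged(self):
        fits = [_make_fit(1.0, 1.0), _make_fit(3.0, 1.0), _make_fit(5.0, 1.0)]
        kept, log = filter_spots(fits, FilterCriteria(), psf_sigma=0.2)
        assert kept == fits
        assert log["accepted"] == 3

    def test_flag_quality_sigma_rules(self):
        crit = FilterCriteria(min_fit_quality=0.5, max_sigma_deviation=0.3)
        fits = [
            _make_fit(1.0, 1.0, flags=("edge",)),
            _make_fit(3.0, 1.0, quality=0.2),
            _make_fit(5.0, 1.0, sigma=0.4),  # 2x the psf width
            _make_fit(7.0, 1.0),
        ]
        kept, log = filter_spots(fits, crit, psf_sigma=0.2)
        assert len(kept) == 1 and kept[0].x == 7.0
        assert log["flagged"] == 1 and log["quality"] == 1 and log["sigma"] == 1

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        fits = [_make_fit(x, y) for x, y in rng.uniform(0, 10, (40, 2))]
        once, _ = filter_spots(fits, FilterCriteria(), psf_sigma=0.2)
        twice, _ = filter_spots(once, FilterCriteria(), psf_sigma=0.2)
        assert twice == once
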