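"""Tests of the autoconvolution mixture analysis (pdfs, fits, errors, maturation)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import lognorm

from toccsl.mixture import (
    BrightnessPDF,
    UnderSampleWarning,
    autoconvolve_pdf,
    binomial_visible_mixture,
    bootstrap_alphas,
    correct_maturation,
    estimate_monomer_pdf,
    fit_mixture,
    mean_oligomer_size,
)
from toccsl.params import PhotophysicsParams, SceneParams
from toccsl.synthetic import simulate_brightness_samples


class TestMonomerPdf:
    def test_kde_close_to_generating_density(self, photo):
        rng = np.random.default_rng(5)
        mu, sig = photo.lognormal_params
        samples = rng.lognormal(mu, sig, 10000)
        est = estimate_monomer_pdf(samples)
        truth = lognorm.pdf(est.grid, sig, scale=np.exp(mu))
        ise = np.trapezoid((est.density - truth) ** 2, est.grid)
        assert ise < 1e-3

    def test_identical_samples_single_peak(self):
        est = estimate_monomer_pdf(np.full(300, 42.0))
        assert est.grid[np.argmax(est.density)] == pytest.approx(42.0, abs=1.0)
        assert np.trapezoid(est.density, est.grid) == pytest.approx(1.0, abs=1e-6)

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError, match=">= 100"):
            estimate_monomer_pdf(np.ones(50) + np.arange(50))

    def test_negative_value_policy(self, monomer_samples):
        bad = np.concatenate([monomer_samples, [-5.0]])
        with pytest.raises(ValueError, match="negative"):
            estimate_monomer_pdf(bad, negative_policy="reject")
        with pytest.warns(UserWarning, match="clipped"):
            est = estimate_monomer_pdf(bad, negative_policy="clip")
        assert np.trapezoid(est.density, est.grid) == pytest.approx(1.0, abs=1e-6)


class TestAutoconvolution:
    def test_identity_at_order_one(self, rho1):
        r = autoconvolve_pdf(rho1, 1)
        assert np.array_equal(r.density, rho1.density)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_moment_scaling_and_normalization(self, rho1, n):
        rn = autoconvolve_pdf(rho1, n)
        assert np.trapezoid(rn.density, rn.grid) == pytest.approx(1.0, abs=1e-6)
        assert rn.mean == pytest.approx(n * rho1.mean, rel=1e-3)
        assert rn.var == pytest.approx(n * rho1.var, rel=5e-3)

    def test_dimer_matches_monte_carlo_sums(self, photo):
        mu, sig = photo.lognormal_params
        grid = np.linspace(0.0, 1300.0, 4096)
        dens = lognorm.pdf(grid, sig, scale=np.exp(mu))
        dens /= np.trapezoid(dens, grid)
        r2 = autoconvolve_pdf(BrightnessPDF(grid=grid, density=dens), 2)
        rng = np.random.default_rng(9)
        draws = np.sort(rng.lognormal(mu, sig, (200000, 2)).sum(axis=1))
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (r2.density[1:] + r2.density[:-1]) * r2.dx)])
        ks = np.max(np.abs(np.interp(draws, grid, cdf) - np.arange(1, draws.size + 1) / draws.size))
        assert ks < 0.005

    def test_short_grid_rejected(self, photo):
        mu, sig = photo.lognormal_params
        grid = np.linspace(0.0, 160.0, 512)  # barely holds the monomer law
        dens = lognorm.pdf(grid, sig, scale=np.exp(mu))
        dens /= np.trapezoid(dens, grid)
        with pytest.raises(ValueError, match="grid too short"):
            autoconvolve_pdf(BrightnessPDF(grid=grid, density=dens), 3)

    def test_order_below_one_rejected(self, rho1):
        with pytest.raises(ValueError, match="n must be"):
            autoconvolve_pdf(rho1, 0)


class TestMixtureFit:
    def test_pure_monomer_self_consistency(self, photo, rho1):
        samples = simulate_brightness_samples(SceneParams(true_alpha=(1.0,)), photo, 2000, 3)
        d = fit_mixture(samples["brightness"].to_numpy(), rho1, n_max=5)
        assert d.alpha[0] > 0.97
        assert d.mean_size < 1.03

    def test_recovers_known_mixture(self, photo, rho1):
        truth = np.array([0.4, 0.3, 0.2, 0.1])
        scene = SceneParams(true_alpha=tuple(truth))
        samples = simulate_brightness_samples(scene, photo, 10000, 17)
        d = fit_mixture(samples["brightness"].to_numpy(), rho1, n_max=4)
        assert np.abs(d.alpha - truth).max() < 0.03
        assert d.alpha.sum() == pytest.approx(1.0, abs=1e-9)

    def test_undersampled_fit_warns_and_flags(self, photo, rho1):
        samples = simulate_brightness_samples(SceneParams(true_alpha=(1.0,)), photo, 500, 3)
        with pytest.warns(UnderSampleWarning):
            d = fit_mixture(samples["brightness"].to_numpy(), rho1, n_max=3)
        assert d.undersampled

    def test_identifiability_degrades_with_monomer_cv(self):
        # wider monomer brightness laws blur the n-mer pdfs into each other
        truth = np.array([0.5, 0.5])
        rmses = []
        for cv in (0.1, 0.3, 0.7):
            photo = PhotophysicsParams(monomer_cv=cv)
            rng = np.random.default_rng(100)
            errs = []
            for _ in range(15):
                cal = photo.draw_monomer_brightness(rng, 1000)
                r1 = estimate_monomer_pdf(cal, n_max=2)
                s = simulate_brightness_samples(SceneParams(true_alpha=(0.5, 0.5)), photo,
                                                750, rng)
                d = fit_mixture(s["brightness"].to_numpy(), r1, n_max=2)
                errs.append(((d.alpha - truth) ** 2).mean())
            rmses.append(np.sqrt(np.mean(errs)))
        assert rmses[0] <= rmses[1] + 0.01
        assert rmses[1] <= rmses[2] + 0.01


class TestBootstrap:
    def test_deterministic_and_calibrated(self, photo, rho1):
        scene = SceneParams(true_alpha=(0.6, 0.4))
        samples = simulate_brightness_samples(scene, photo, 750, 5)["brightness"].to_numpy()
        se_a = bootstrap_alphas(samples, rho1, n_max=3, seed=2)
        se_b = bootstrap_alphas(samples, rho1, n_max=3, seed=2)
        assert np.array_equal(se_a, se_b)
        # within a factor two of the spread over independently regenerated datasets
        fits = np.array([
            fit_mixture(
                simulate_brightness_samples(scene, photo, 750, 600 + i)["brightness"].to_numpy(),
                rho1, n_max=3,
            ).alpha
            for i in range(40)
        ])
        ensemble_sd = fits.std(axis=0, ddof=1)
        ratio = se_a[:2] / ensemble_sd[:2]  # alpha_3 is ~0 and both spreads tiny
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)

    def test_too_few_reps_rejected(self, monomer_samples, rho1):
        with pytest.raises(ValueError, match="reps"):
            bootstrap_alphas(monomer_samples, rho1, reps=1)


class TestMeanSizeAndMaturation:
    @pytest.mark.parametrize(
        "alpha,expected",
        [((1.0, 0.0, 0.0), 1.0), ((0.0, 1.0, 0.0), 2.0), ((0.5, 0.5), 1.5)],
    )
    def test_mean_size_values(self, alpha, expected):
        assert mean_oligomer_size(alpha) == pytest.approx(expected)

    def test_mean_size_requires_normalization(self):
        with pytest.raises(ValueError, match="normalized"):
            mean_oligomer_size((0.5, 0.2))

    def test_full_maturation_is_identity(self):
        alpha = np.array([0.2, 0.5, 0.3])
        assert np.allclose(correct_maturation(alpha, 1.0), alpha)

    def test_pure_dimer_worked_example(self):
        # visible (1/3, 2/3) at p = 0.8 comes from pure dimers
        rec = correct_maturation(np.array([1 / 3, 2 / 3]), 0.8)
        assert np.allclose(rec, [0.0, 1.0], atol=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
        st.sampled_from([0.6, 0.8, 0.95]),
    )
    def test_forward_then_invert_round_trip(self, weights, p):
        alpha = np.asarray(weights) / np.sum(weights)
        observed = binomial_visible_mixture(alpha, p)
        assert np.abs(correct_maturation(observed, p) - alpha).max() < 1e-6

    def test_ill_conditioned_p_rejected(self):
        with pytest.raises(ValueError, match="condition number"):
            correct_maturation(np.array([0.2, 0.2, 0.2, 0.2, 0.2]), 0.01)
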