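"""Tests of the ground-truth simulator: photophysics, imaging, protocol, exchange."""

import numpy as np
import pytest
from scipy import stats

from toccsl.params import ImagingParams, PhotophysicsParams, ProtocolTiming, Rect, SceneParams
from toccsl.synthetic import (
    OligomerPopulation,
    exchange_subunits,
    render_frame,
    simulate_brightness_samples,
    simulate_frap_curve,
    simulate_repetitive_brightness_series,
    simulate_repetitive_series,
    simulate_toccsl_run,
    thinned_visible_pmf,
)


class TestBrightnessSamples:
    def test_pure_monomer_identity(self, photo):
        scene = SceneParams(true_alpha=(1.0,))
        df = simulate_brightness_samples(scene, photo, 20000, seed=1)
        assert (df["k_active"] == 1).all()
        assert (df["n_true"] == 1).all()
        se = df["brightness"].std() / np.sqrt(len(df))
        assert abs(df["brightness"].mean() - 100.0) < 3 * se

    def test_dimer_binomial_thinning(self):
        # pure dimers, p = 0.8: visible k=1 with prob 2*0.8*0.2/0.96, k=2 with 0.64/0.96
        scene = SceneParams(true_alpha=(0.0, 1.0))
        photo = PhotophysicsParams(maturation_p=0.8)
        df = simulate_brightness_samples(scene, photo, 150000, seed=2)
        frac1 = (df["k_active"] == 1).mean()
        assert frac1 == pytest.approx(1.0 / 3.0, abs=0.01)
        assert (df["k_active"] == 2).mean() == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_deterministic_given_seed(self, photo):
        scene = SceneParams(true_alpha=(0.5, 0.5))
        a = simulate_brightness_samples(scene, photo, 500, seed=7)
        b = simulate_brightness_samples(scene, photo, 500, seed=7)
        assert a.equals(b)

    def test_rejects_invalid_inputs(self, photo):
        with pytest.raises(ValueError, match="n must be"):
            simulate_brightness_samples(SceneParams(), photo, 0, seed=1)
        with pytest.raises(ValueError, match="sum to 1"):
            SceneParams(true_alpha=(0.5, 0.4))
        with pytest.raises(ValueError, match=">= 0"):
            SceneParams(true_alpha=(1.5, -0.5))


class TestRenderFrame:
    def test_blank_without_emitters_or_noise(self):
        im = ImagingParams(background_rate=0.0, read_noise_sd=0.0)
        frame = render_frame(np.empty((0, 2)), np.empty(0), im, (3.0, 3.0), rng=None)
        assert frame.shape == (19, 19)
        assert np.all(frame == 0.0)

    def test_flux_conservation_noiseless(self):
        im = ImagingParams(background_rate=0.0, read_noise_sd=0.0)
        frame = render_frame(np.array([[2.0, 1.8]]), np.array([250.0]), im, (4.0, 4.0), rng=None)
        assert frame.sum() == pytest.approx(250.0, rel=0.01)
        assert frame.min() >= 0.0

    def test_shot_noise_preserves_mean_flux(self, imaging):
        im = ImagingParams(read_noise_sd=0.0, background_rate=0.0)
        rng = np.random.default_rng(11)
        totals = [
            render_frame(np.array([[2.0, 2.0]]), np.array([100.0]), im, (4.0, 4.0), rng).sum()
            for _ in range(1000)
        ]
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 100.0) < 3 * se


class TestToccslRun:
    def test_no_bleaching_keeps_emitter_set(self, small_scene, imaging, small_timing):
        photo = PhotophysicsParams(bleach_survival=1.0 - 1e-12)
        run = simulate_toccsl_run(small_scene, photo, imaging, small_timing, seed=3)
        pre = run.truth["pre_bleach"]
        rec = run.truth["toccsl"]
        assert len(rec) == len(pre)
        assert rec["n_active"].sum() == pre["n_active"].sum()

    def test_complete_bleach_empties_roi(self, imaging):
        scene = SceneParams(true_alpha=(1.0,), density=1.0, diffusion_coeff=0.0,
                            mobile_fraction=0.0, field_size=(12.0, 12.0))
        timing = ProtocolTiming(roi=Rect(3.0, 3.0, 9.0, 9.0), t_post=40.0, t_recovery=40.0)
        run = simulate_toccsl_run(scene, PhotophysicsParams(bleach_survival=0.0),
                                  imaging, timing, seed=4)
        for frame_name in ("post_bleach", "toccsl"):
            t = run.truth[frame_name]
            inside = (t["x"] >= 3) & (t["x"] < 9) & (t["y"] >= 3) & (t["y"] < 9)
            assert inside.sum() == 0

    def test_entrants_carry_population_stoichiometry(self, imaging):
        # label mix is conserved by diffusion: spots recovering into the ROI
        # sample the unbleached population's active-count distribution
        alpha = (0.45, 0.35, 0.15, 0.05)
        scene = SceneParams(true_alpha=alpha, density=0.8, diffusion_coeff=1.0,
                            mobile_fraction=1.0, field_size=(16.0, 16.0))
        timing = ProtocolTiming(roi=Rect(4.0, 4.0, 12.0, 12.0), t_recovery=2000.0)
        counts = np.zeros(4)
        for seed in range(25):
            run = simulate_toccsl_run(scene, PhotophysicsParams(), imaging, timing, seed)
            t = run.truth["toccsl"]
            ins = t[(t.x >= 4) & (t.x < 12) & (t.y >= 4) & (t.y < 12)]
            counts += np.bincount(ins["n_active"], minlength=5)[1:]
        frac = counts / counts.sum()
        assert np.abs(frac - np.asarray(alpha)).max() < 0.05

    def test_roi_outside_field_rejected(self, small_scene, photo, imaging):
        timing = ProtocolTiming(roi=Rect(8.0, 8.0, 14.0, 14.0))
        with pytest.raises(ValueError, match="inside the field"):
            simulate_toccsl_run(small_scene, photo, imaging, timing, seed=1)


class TestExchange:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_swaps_conserve_sizes_and_totals(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        size = rng.integers(1, 5, n)
        act = rng.binomial(size, 0.7)
        pop = OligomerPopulation(x=np.zeros(n), y=np.zeros(n), size=size.astype(np.int64),
                                 n_active=act.astype(np.int64),
                                 mobile=np.ones(n, bool), bounds=Rect(0, 0, 1, 1))
        size0, act0 = pop.size.copy(), int(pop.n_active.sum())
        exchange_subunits(pop, 5000, rng)
        assert np.array_equal(pop.size, size0)
        assert int(pop.n_active.sum()) == act0
        assert np.all(pop.n_active >= 0) and np.all(pop.n_active <= pop.size)

    def test_no_exchange_keeps_visible_distribution(self, photo):
        tables, _ = simulate_repetitive_brightness_series(
            (0.5, 0.3, 0.2), photo, 3000, 8, 60.0, exchange_rate=0.0, seed=5
        )
        first = np.bincount(tables[0]["k_active"], minlength=4)[1:] / len(tables[0])
        last = np.bincount(tables[-1]["k_active"], minlength=4)[1:] / len(tables[-1])
        assert np.abs(first - last).max() < 0.05

    def test_fast_exchange_reaches_binomial_mixing(self, photo):
        alpha = (0.45, 0.35, 0.15, 0.05)
        tables, summary = simulate_repetitive_brightness_series(
            alpha, photo, 3000, 10, 60.0, exchange_rate=0.1, seed=6
        )
        f = summary["f_per_run"][-1]
        assert 0.4 < f < 0.65  # ~50% of fluorophores bleached over ten runs
        pmf = thinned_visible_pmf(alpha, f)
        last = tables[-1]
        obs = np.zeros((4, 4))
        for n_true, k in zip(last["n_true"], last["k_active"]):
            obs[n_true - 1, k - 1] += 1
        expected = pmf * len(last)
        mask = expected > 5
        chi2 = ((obs[mask] - expected[mask]) ** 2 / expected[mask]).sum()
        p = stats.chi2.sf(chi2, mask.sum() - 1)
        assert p > 0.01

    def test_repetitive_image_series_reuses_population(self, imaging):
        scene = SceneParams(true_alpha=(1.0,), density=0.2, diffusion_coeff=0.3,
                            mobile_fraction=1.0, field_size=(10.0, 10.0))
        timing = ProtocolTiming(roi=Rect(3.0, 3.0, 7.0, 7.0), t_recovery=1000.0,
                                n_runs=3, run_interval=30.0)
        runs = simulate_repetitive_series(scene, PhotophysicsParams(), imaging, timing, seed=8)
        assert len(runs) == 3
        active = [r.truth["pre_bleach"]["n_active"].sum() for r in runs]
        assert active[0] >= active[1] >= active[2]  # bleaching only removes

    def test_series_needs_two_runs(self, small_scene, photo, imaging):
        timing = ProtocolTiming(roi=Rect(3.0, 3.0, 9.0, 9.0), n_runs=1)
        with pytest.raises(ValueError, match="n_runs"):
            simulate_repetitive_series(small_scene, photo, imaging, timing, seed=1)


class TestFrapCurve:
    def test_immobile_gives_flat_noise(self):
        c = simulate_frap_curve(0.0, 0.2, 0.01, np.arange(0.0, 20.0, 0.5), seed=1)
        assert np.abs(c.normalized_intensity).max() < 5 * 0.01

    def test_fully_mobile_asymptote(self):
        t = np.arange(0.0, 100.0, 1.0)
        c = simulate_frap_curve(1.0, 0.5, 0.0, t, seed=1)
        assert c.normalized_intensity[-1] == pytest.approx(1.0, abs=1e-6)
        assert c.normalized_intensity[0] == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="recovery_rate"):
            simulate_frap_curve(0.5, -0.1, 0.0, np.arange(5.0), seed=1)
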