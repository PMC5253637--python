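# toccsl

Single-molecule brightness stoichiometry for membrane proteins: TOCCSL and
FRAP analysis with a ground-truth TIRF simulator.

## The problem

How many subunits travel together in a membrane-protein complex? At typical
expression levels the plasma membrane is so densely labelled that individual
complexes cannot be resolved. **TOCCSL** ("thinning out clusters while
conserving stoichiometry of labeling") solves this by photobleaching a small
rectangular region of the membrane with a strong laser pulse and imaging the
*onset* of fluorescence recovery: the first unbleached complexes that diffuse
back into the bleached region appear as isolated, diffraction-limited spots
whose integrated brightness `B` reports how many active fluorophores they
carry. This package implements the complete analysis chain for such
experiments, for researchers doing single-molecule TIRF microscopy of
oligomerizing membrane proteins (transporters, receptors, channels).

## The method

Each detected spot is fitted with a pixel-integrated 2-D Gaussian; the fitted
volume above background is the spot brightness `B`. The pdf of a single active
fluorophore, ρ₁(B), is calibrated from cells bleached down to sparse single
fluorophores. Because brightness is additive over co-diffusing fluorophores,
the pdf of an N-mer is the N-fold autoconvolution ρ_N = ρ₁ ∗ ⋯ ∗ ρ₁, and the
observed brightness pdf is fitted as the constrained linear combination

    ρ(B) = Σ_N α_N ρ_N(B),    α_N ≥ 0,  Σ_N α_N = 1,

whose weights α_N are the fractions of complexes with N co-diffusing active
fluorophores. The package reports α with half-sample bootstrap errors
(s.d. over 100 refits of 50% subsamples, divided by √2), the mean oligomer
size Σ N·α_N, and an inversion of the binomial thinning caused by incomplete
fluorophore maturation (a fluorophore is active only with probability p, so α
underestimates the true subunit count).

Around the core fit the package provides:

- **Protocol orchestration** — post-bleach completeness gate, per-run
  stoichiometry inside the bleach ROI, surface density from the pre-bleach
  frame (mean intensity / single-molecule brightness / membrane area fraction).
- **Repetitive TOCCSL** — one run per minute on the same region; stable
  complexes lose spots but keep their brightness distribution, whereas subunit
  exchange mixes bleached protomers into visible complexes and shifts the
  distribution toward smaller sizes. A weighted regression of mean size on run
  time yields a stable / exchanging / inconclusive verdict.
- **FRAP** — bounded fit of I(t) = α(1 − e^{−kt}) for the mobile fraction α.
- **Synthetic data** — a full TIRF simulator (lognormal monomer brightness,
  binomial maturation, Brownian diffusion with mobile/immobile split,
  ROI bleaching, Poisson shot + Gaussian read noise, Poisson-clocked pairwise
  subunit exchange) with exact ground-truth tracking, used to validate every
  stage.

## Worked example

```python
import numpy as np
from toccsl import (PhotophysicsParams, SceneParams, estimate_monomer_pdf,
                    fit_mixture, bootstrap_alphas, correct_maturation)
from toccsl.synthetic import simulate_brightness_samples

photo = PhotophysicsParams()                  # monomer: mean 100 counts, CV 0.3
rng = np.random.default_rng(0)
rho1 = estimate_monomer_pdf(photo.draw_monomer_brightness(rng, 1000))

scene = SceneParams(true_alpha=(0.4, 0.3, 0.2, 0.1))   # 40% monomers ... 10% tetramers
spots = simulate_brightness_samples(scene, photo, n=10000, seed=1)

dist = fit_mixture(spots["brightness"].to_numpy(), rho1, n_max=4)
se = bootstrap_alphas(spots["brightness"].to_numpy(), rho1, n_max=4, seed=2)
print("alpha:", dist.alpha.round(3), "+/-", se.round(3))
print("mean oligomer size:", round(dist.mean_size, 3))
```

prints

```
alpha: [0.385 0.304 0.194 0.117] +/- [0.004 0.004 0.004 0.003]
mean oligomer size: 2.042
```

i.e. the fitted fractions recover the simulated mixture (0.4, 0.3, 0.2, 0.1)
to within ±0.02, and the mean number of co-diffusing active fluorophores is
≈ 2.0 (truth exactly 2.0). If only 80% of fluorophores had matured,
`correct_maturation(dist.alpha, 0.8)` would undo the resulting underestimate.

A command-line interface covers the same pipeline on files
(`toccsl simulate | calibrate-monomer | toccsl | series | frap | density`);
every output embeds the configuration hash and seed.

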