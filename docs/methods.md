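# Methods

This note documents the models, estimators and numerical choices implemented
in `toccsl`, the assumptions behind them, and what the synthetic-data
validation does and does not demonstrate about real recordings.

## Brightness model and the mixture fit

A diffraction-limited spot produced by a complex with k active fluorophores
has integrated brightness equal to the sum of k independent single-fluorophore
brightnesses. The single-fluorophore (monomer) brightness is modelled as
lognormal with mean `monomer_mean_brightness` (default 100 counts) and
coefficient of variation `monomer_cv` (default 0.3): strictly positive and
right-skewed like measured single-fluorophore brightness distributions, with
two interpretable parameters. Under this additivity, the N-mer pdf is the
N-fold autoconvolution of the monomer pdf ρ₁, and the observed spot-brightness
pdf is the simplex-constrained linear combination ρ(B) = Σ α_N ρ_N(B). The fit
minimizes the least-squares distance between the kernel-smoothed sample pdf
and the mixture on a common grid (the readout of the experiment is a pdf, not
a likelihood over raw counts); α_N are the fractions of complexes with N
co-diffusing *active* fluorophores.

Numerics:

- **Grid.** 2¹² uniform points on [0, (n_max + 1) · max(monomer sample)],
  which holds the support of every autoconvolution up to n_max (default 5,
  since complexes from monomers up to pentamers are observed in this class of
  experiment) plus one spare order. Autoconvolution uses zero-padded FFTs; the
  operation refuses grids that would truncate more than 10⁻⁴ of the mass of
  ρ_N.
- **Kernel smoothing.** Empirical densities are linear-binned; smoothing is a
  Gaussian kernel with Silverman's bandwidth computed once on the monomer
  calibration and reused unchanged for the mixture sample pdf. The mixture
  components are built by autoconvolving the *pre-smoothing* binned monomer
  density and applying the same single kernel afterwards. This makes the model
  components and the sample pdf carry exactly one kernel's worth of smoothing
  each, so the smoothing bias cancels at every order N. (Autoconvolving the
  already-smoothed ρ₁ would smooth ρ_N N times — variance N·(σ² + h²) instead
  of N·σ² + h² — and bias the fit toward lower orders.) A reflection boundary
  at B = 0 prevents leakage of density mass to negative brightness.
- **Constrained solve.** The least-squares problem over {α ≥ 0, Σα = 1} is
  solved exactly by enumerating candidate support sets (at most 2^n_max − 1
  small KKT systems). This is deterministic, machine-precision, and exposes
  degeneracy directly: when several supports tie in objective, the solution
  with the smallest mean oligomer size is reported (the most conservative
  oligomerization claim) and the result is flagged degenerate.
- **Errors.** Half-sample bootstrap: 100 refits of random 50% subsamples; the
  reported standard error is the s.d. across refits divided by √2, the
  correction that maps the spread of half-sample estimates to that of the full
  sample. Both the divisor and the subsample fraction are configurable and
  echoed in outputs.
- **Sample size.** Fits below 750 spots are returned with an explicit
  under-sample warning and flag; 750 is the established minimum for reliable
  n-mer fractions in this analysis and pooling spots across cells to reach it
  is supported everywhere.

## Maturation correction

A protomer's fluorophore is active with probability p (incomplete maturation),
so observed active-fluorophore counts underestimate true subunit counts.
Visible spots (k ≥ 1) with true size N have k ~ Binomial(N, p) conditioned on
k ≥ 1, and the visible-spot size composition is reweighted by the visibility
1 − (1−p)^N. `correct_maturation` inverts this linear model on the simplex
(plain solve when feasible, otherwise the exact constrained solver) and
rescales by the visibility weights. The inversion refuses p small enough that
the thinning matrix condition number exceeds 10⁸. The default maturation
probability in the simulator is 1.0 — the published value for the fluorescent
protein used in this class of experiment is not established, so fixtures that
exercise the correction set p explicitly (0.6–0.95).

## Spot detection and fitting

Detection: a band-pass matched filter (Gaussian at the PSF scale minus a 5×
coarser background estimate), local maxima above `detection_threshold` × the
noise s.d. of the filtered image. The noise is estimated from negative
deviations only (signals contribute positive structure); when only part of a
frame is structure-free — the interior of a freshly bleached region next to a
dense unbleached surround — the caller passes a noise level measured there,
which is what the protocol layer does automatically.

Fitting: bounded least squares of a *pixel-integrated* Gaussian (error
functions per pixel, matching how a camera integrates flux) plus constant
background. The amplitude parameter therefore *is* the integrated brightness
B; integrated volume rather than peak amplitude is the statistic because it is
additive across co-diffusing fluorophores and insensitive to small width
misfit. Bounds: amplitude ≥ 0, σ ∈ [0.5, 2] × the nominal PSF width. The fit
window half-width defaults to 4 PSF sigmas: with a 3-sigma window the B ≥ 0
boundary visibly biases dim spots upward (measured +8 counts at B = 60 under
default camera noise) because too few pure-background pixels constrain the
baseline; 4 sigmas reduces both the estimator s.d. (~37 → ~30 counts) and the
boundary bias.

Selection: edge- and failed-fit flags, border margin, fit-quality (R²) floor,
PSF-width outlier rejection, and removal of *both* members of any pair closer
than 4 PSF sigmas (their brightness would mix and corrupt the stoichiometry).
Filtering is idempotent and logs counts removed per rule.

Remaining known bias: spots dimmer than the detection threshold are missed,
so the dimmest part of the monomer population is under-represented. Because
the monomer calibration is measured with the same pipeline, the same selection
acts on ρ₁ and largely cancels in the fit; the residual effect is visible as a
small transfer between α₁ and α₂ in the end-to-end benchmark while the mean
oligomer size stays within a few percent.

## TOCCSL protocol analysis

Timing defaults follow the published protocol: pre-bleach frame, 50 ms to a
600–800 ms bleach pulse, post-bleach check 40 ms after the pulse, recovery
image after an adjustable 1.5–12 s.

- **Completeness gate.** The positive band-pass energy inside the ROI after
  bleaching, corrected by the analytic noise floor of the positive part of
  zero-mean Gaussian noise, is compared with the pre-bleach value; runs above
  5% residual structure are rejected and no stoichiometry is ever reported
  from them. An ROI with no structure before bleaching passes vacuously with a
  warning.
- **Recovery-frame analysis** runs on a crop (ROI + fit-window margin): only
  molecules that re-entered the bleached region are isolated single spots.
  Only the mobile fraction of the population is analysable by construction —
  immobile complexes never re-enter — and a run whose accepted spot count is
  below `min_spots_per_run` (default 50) is flagged rather than silently
  dropped, so cells can be pooled.
- **Surface density** = mean pre-bleach intensity per µm² divided by the mean
  single-molecule brightness and by the membrane area fraction (for
  ER–plasma-membrane junctions, where only a fraction of the footprint is
  membrane, the area fraction is an input measured elsewhere, e.g. from
  super-resolution images).
- **Repetitive series.** One run per minute on the same region. Stable
  complexes: spot numbers fall, the brightness distribution does not change.
  Exchanging complexes: bleached protomers mix into visible complexes, the
  distribution shifts toward smaller sizes. The verdict statistic is the slope
  of mean oligomer size against run time from a weighted linear regression
  (weights 1/SE² from the per-run bootstrap): a single powered test rather
  than per-fraction comparisons. "Exchanging" requires a negative slope
  significant one-sidedly at 0.05; otherwise "stable" (the result carries the
  smallest detectable slope as a power report), or "inconclusive" when more
  than half the runs are under-sampled. No absolute exchange rate constant is
  estimated — the readout is deliberately qualitative.

## FRAP and density quantification

The recovery of the central 50% (by linear dimension) of the bleached region,
normalized between the first post-bleach frame (0) and the pre-bleach frame
(1), is fitted with the single-exponential saturating form
I(t) = α (1 − e^{−kt}) with α bounded to [0, 1]. The plateau α is the mobile
fraction; k is a nuisance parameter, and no diffusion coefficient is derived
from it. The single-exponential form with zero immediate offset is an
assumption of this package: the experimentally fitted recovery equation is
only specified up to its plateau in the source protocols.

## The simulator: what it emulates and what it does not

`toccsl.synthetic` renders diffraction-limited emitters (exact
pixel-integrated Gaussian PSF, flux-conserving), Poisson shot noise on signal
plus background, linear camera gain and Gaussian read noise; oligomers diffuse
as rigid units by per-step Gaussian displacements with reflecting boundaries
on a field padded by the PSF extent (so border flux is unbiased), with a
binary mobile/immobile split. Bleaching deactivates fluorophores of complexes
inside the ROI (survival probability per exposure, sub-stepped across the
bleach pulse so molecules transiting the ROI are bleached too). Subunit
exchange is a Poisson-clocked pairwise swap of one random subunit between two
random complexes — the simplest mechanism that conserves complex sizes and
total active-fluorophore count while realizing complete mixing, without
modelling assembly energetics. Its closed-form limit (each subunit active
independently with probability f, conditioned visible) is used as an oracle.

Default study conditions used by the validation experiments: monomer mean
brightness 100 counts, CV 0.3; pixel 0.16 µm, PSF σ 0.2 µm, background 5
counts/px, read noise 1.5 counts, gain 1 (no EM excess noise — the analysis
uses relative brightness only); D = 0.5 µm²/s, 80% mobile; a 10×10 µm ROI in
a 20×20 µm field with 6 s recovery; oligomer surface density 0.35 µm⁻² for
TOCCSL runs, low enough that recovery entrants are resolvable single spots, as
the protocol itself requires (at high densities unresolved entrant pairs
masquerade as higher-order complexes). The repetitive-series generator bleaches
each complex with per-run probability 1 − 0.5^(1/10), reproducing the ~50%
depletion of active fluorophores over a ten-run series, and pools 750 spots
per run as pooling across cells does in practice.

Not emulated: photoblinking, EMCCD excess noise, axial (z) structure, membrane
topography of ER–PM junctions, drift, and assembly thermodynamics (exchange is
phenomenological). Passing validation therefore demonstrates correctness of
the estimators under the stated photophysical and geometric model, not
robustness to blinking artefacts or non-Gaussian PSFs.

## Validation experiment sizes

The experiments in `toccsl.validation` (run by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 10⁶ Monte-Carlo draws per autoconvolution order;
100 independent datasets of 750 spots (fresh 1000-spot monomer calibration
each) for mixture recovery; 200 random simplex vectors per maturation
probability; pooling to ≥750 accepted spots through the imaging pipeline
(~120 simulated cells); 50 + 50 ten-run repetitive series of 4000 complexes;
100 FRAP curves (noise s.d. 0.02); and rendered frames at 25–800 emitters/µm².
These sizes give sampling errors comfortably below the documented tolerances
while keeping the whole validation suite at about two minutes on one CPU.
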