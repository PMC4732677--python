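# Methods

This note documents the models, estimators, numerical choices and
limitations behind `beachmix`, in the order the pipeline applies them.

## Isotope data model

All values are δ-notation per-mil deviations, δ = (R_sample/R_standard −
1) × 1000, with ¹³C/¹²C referenced to Vienna PeeDee Belemnite and
¹⁵N/¹⁴N to atmospheric N₂. Signatures outside δ¹³C ∈ [−60, 10] ‰ or
δ¹⁵N ∈ [−10, 30] ‰ trigger a warning but are never rejected: the bounds
are a plausibility screen for coastal tissue, not a validity rule.
Summaries report the sample SD (n−1 denominator) and record it as missing
for n = 1. Instrument-level between-sample variation (on the order of
±0.1 ‰ for certified standards) is not propagated as a separate error
term anywhere downstream; it is far below the biological SDs carried by
the sources.

Mixed wrack signatures are dry-mass-proportion-weighted arithmetic means
of the component signatures, with weights renormalized to 1.

## Trophic enrichment factor (TEF)

The site nitrogen TEF is the mean of the three consumer−source mean δ¹⁵N
differences; its SD is the sample SD (n−1, n = 3) of those differences.
Carbon enrichment is fixed at (0, 0) ‰. The estimator is
translation-equivariant and weights the three sources equally — diet
shares are unknown at TEF-estimation time.

**Known limitation.** Averaging differences is unbiased only when the
true diet is balanced: the estimator's expectation is
TEF_true + (Σ_k p_k s_N,k − mean_k s_N,k), so a consumer eating mostly
the ¹⁵N-richest (or poorest) source receives a TEF biased by up to the
spread of the source δ¹⁵N means. With sources spanning ~2 ‰ in δ¹⁵N the
bias stays below ~1 ‰, but it propagates into the inferred diet. The
trophic-position consistency check in the acceptance suite therefore
supplies the true enrichment, isolating the downstream stack from this
estimator property; the property itself is verified analytically and
numerically in the test suite's diagnostics.

## Missing-amphipod imputation

Amphipod tissue can be unobtainable where wrack is scarce or dry. The
imputed signature takes the site's mixed wrack δ¹³C unchanged (no trophic
fractionation assumed between wrack and its detritivore) and a δ¹⁵N from
an ordinary-least-squares calibration of amphipod on wrack δ¹⁵N, fitted
once across all sites with both materials (≥ 3 pairs required). Imputed
summaries carry n = 0, a persistent `imputed` flag in every output, and
an SD equal to the mean of the measured per-site amphipod SDs (fallback
0.5 ‰ if none exist) — the mixing model needs a source SD and the
calibration provides none.

## Bayesian mixing model

Three sources, two isotopes, one consumer observation ("solo"):

    δ_j ~ Normal( Σ_k p_k (s_jk + c_jk),  Σ_k p_k²(σ_jk² + τ_jk²) + ε_j² )

Dirichlet(α) prior on p (all-ones default → uniform on the simplex);
Uniform(0, 20 ‰) prior on each residual SD ε_j when sampled. No
elemental-concentration weighting is applied. Any source or combined
source+TEF SD of exactly zero is floored at 0.01 ‰ inside the likelihood
so degenerate synthetic inputs keep the posterior proper.

**Residual error and the solo setting.** With one observation per isotope
the residual SD is unidentifiable: under the vague Uniform(0, 20) prior
its posterior retains a median of several ‰, which inflates the mixture
variance and pulls every diet posterior toward (⅓, ⅓, ⅓) (we measured a
recovery MAE of ~0.18 against ~0.05 with ε fixed). For this reason the
pipeline's default is the process-error-only likelihood (ε ≡ 0),
configurable via `PipelineConfig.fixed_resid_sd`; sampling ε remains
available in `sample_posterior` for multi-observation uses. This mirrors
standard practice that single-consumer mixing runs exclude residual
error.

**Sampler.** Component-wise random-walk Metropolis on the additive-log-
ratio transform of p (2 free coordinates) and, when sampled, the log
residual SDs. The transform's Jacobian (Σ log p_k, plus log ε for the
log-SD move) is included. Proposal scales start at 0.5 and adapt every
100 iterations during burn-in (×1.25 above 50% acceptance, ×0.8 below
20%), then freeze; chains are seeded and byte-reproducible.
Initialization is the uniform diet and ε = 1 ‰. The default schedule —
100 000 iterations, 10 000 burn-in, thin 15 — retains exactly
⌊90 000/15⌋ = 6 000 draws per consumer; the multi-chain recovery studies
in the acceptance suite run 20 000/2 000/15 (1 200 draws), which matches
the full schedule's posterior means to well within the tolerances tested.

Correctness is checked two independent ways: `log_posterior` against a
term-by-term density computation, and the sampler against dense trapezoid
grid integration on a two-source/one-isotope reduction (agreement within
0.02 on the posterior mean).

Site-level diet is the arithmetic mean of the individual posterior-mean
proportions, so site rows remain on the simplex.

## Trophic position

TP = (δ¹⁵N_consumer − δ¹⁵N_resource)/Δ + 2, with Δ = 2.3 ‰ per trophic
level (a configurable literature constant for aquatic systems) and the
resource baseline Σ_k p_k δ¹⁵N_k using the site's mean diet and source
means. δ¹⁵N_consumer is the site mean over individual crabs. Proportions
must be non-negative and sum to 1 within 10⁻⁶ (then renormalized
exactly). Note that the classic worked illustration of this baseline
(0.325, 0.325, 0.350 on sources 5.3, 3.8, 5.9 ‰) is usually quoted as
5.04 ‰; exact arithmetic gives 5.0225 ‰ and the package computes
exactly — the two differ only in rounding.

## Gradient regression battery

Diet proportions are arcsine-square-root transformed (radians); densities
are log₁₀ transformed, with exact zeros offset by +0.01 and flagged
rather than silently shifted. Stepwise regression is forward selection
with backward removal on partial F statistics (defaults F-to-enter 4.0,
F-to-remove 3.9, the conventional defaults of the originating desktop
statistics packages; a p-value mode with p ≤ 0.05 enter / p > 0.10 remove
is also provided since the thresholds used historically are often
unstated). Near-collinear candidates (unexplained variance fraction
< 10⁻¹⁰ against the current design) are skipped with a warning and a
visited-subset guard ensures termination. Reports include standardized
coefficients (b·SD(x)/SD(y)), F-to-remove for included and F-to-enter at
the final step for excluded variables.

Nonlinear fits — the 3-parameter Gaussian peak a·exp(−½((x−x₀)/b)²) and
the 2-parameter saturating hyperbola a(1−e^(−bx)) — use
`scipy.optimize.least_squares` from 5 deterministic starts spanning the
data range (tolerances 10⁻¹²), returning the lowest-SSE solution, so the
result never has a higher SSE than any start. R² = 1 − SS_res/SS_tot may
be negative for a bad nonlinear fit and is reported as-is with a flag;
model F uses 2 (Gaussian) or 1 (hyperbola) model df. Constant responses
and fitted spreads far beyond the data range raise a degenerate-fit
error rather than returning a meaningless optimum. Per-model row
exclusion is supported for influence checks (dropping a site from one
fit changes only that fit's n).

## Synthetic-data generator

The simulator emulates a 16-site beach-width gradient (defaults 15.7 to
106.6 m, evenly spaced with optional jitter). Slope (17.2 → 2.4°) and
median grain size (1.5 → 0.1875 mm) decline linearly with width, each
with lognormal site-level scatter of 0.5 — chosen so their correlation
with width is ≈ −0.7, a realistic degree of covariation: real surveys
include intermediate-width beaches with the finest sediments of all, so
the physical covariates are related to width but far from deterministic
functions of it. Wrack biomass follows the amphipod availability curve
(Gaussian centred at 40 m, spread 12 m — the "intermediate width" band —
scaled to 400 g at peak) and burrow density a Gaussian at 40 m, spread
15 m, 25 per 100 m² at peak, both noisy and floored at 0.

True diets are the normalized availability scores (mole crab linear 1→0
across the range, coquina the mirror image, amphipod the Gaussian); an
all-zero site falls back to the uniform diet. Source means per site are
the taxon bases — δ¹³C (−14.8, −17.9, −21.5) ‰, δ¹⁵N (5.3, 3.8, 5.9) ‰
for mole crab/amphipod/coquina — plus independent Normal(0, 0.5 ‰) site
drift. Replicates (2–9 per site × taxon) are Normal with SD 0.5 ‰;
consumers (3–7 per site) are drawn from the mixing model's closed-form
forward distribution with true TEF (2.3, 0.3) ‰ and residual SD 0.3 ‰
per isotope. Wrack component pairs are constructed so their proportional
mixture inverts the nitrogen calibration (true slope/intercept
1.433/2.242) around the site's amphipod mean, letting the imputation
path be exercised with known truth; a configurable number of sites has
amphipod tissue withheld. Each simulation stage draws from an
independent, seed-derived RNG substream, so identical configurations
produce byte-identical output files.

**What the simulator does not emulate** — and hence what passing tests do
not show about field data: temporal dynamics (tides, storms, seasons),
spatial autocorrelation along the coast, consumer movement between
beaches, carrion or microphage subsidies, selectivity (diet tracks
availability exactly), isotopic routing/turnover in tissue, and
non-Normal replicate error.

## Validation scenarios and problem sizes

The acceptance checks in `tests/test_acceptance.py` use: the full
100k-iteration schedule for the retention law (one consumer); a
20-site study with source centroids ≥ 3 ‰ apart per isotope *and* a
non-degenerate mixing triangle for diet recovery (collinear sources in
(δ¹³C, δ¹⁵N) space leave the diet unidentifiable no matter how separated
they are — the standard mixing-polygon requirement); a low-noise 16-site
scenario with true TEF = Δ = 2.3 ‰ for trophic-position consistency, so
the ±0.15 band measures pipeline bias and posterior propagation rather
than the sampling noise of a 3–7-crab site mean; and 100 seeded
replicates at diet-observation noise equal to half the across-site SD of
the transformed signal ("effect size 2× noise SD") for gradient-direction
recovery.

## Known limitations

* Two tracers bound what any three-source mixing model can resolve;
  credible intervals, not point diets, are the honest output.
* The TEF difference-averaging estimator is biased under uneven diets
  (see above).
* The stepwise battery inherits the usual caveats of stepwise inference:
  selection-conditioned p-values are optimistic; the thresholds are
  conventions, and both F- and p-modes are provided.
* Site-level TP uses the site-mean consumer signature; with 3–7
  individuals its sampling SD is ~0.1–0.2 trophic units under realistic
  isotope noise.
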