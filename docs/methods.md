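# Methods

## Model and estimation

`nettemp` treats each measurement occasion as an independent sample from an
Ising model P(x) = exp(−βH(x))/Z over p binary items, with potential
H(x) = −(τᵀx + ½xᵀΩx). The sign convention makes positive thresholds and
positive edges favor endorsement and alignment, so that "cooling"
(increasing β) concentrates probability on aligned, low-energy
configurations. The Boltzmann constant is absorbed into β, hence
temperature is exactly T = 1/β.

Groups (occasions) are fitted jointly by maximum likelihood under four
nested equality-constraint levels (saturated; equal edges; equal edges and
thresholds; equal everything). β is a pure scale on the potential, so it is
unidentified when nothing is shared: the saturated and fully tied models fix
every β to 1, and the two intermediate levels fix β₁ = 1 and free
β₂…β_G — the same anchoring logic as latent-scale identification in
structural equation modeling. β is parameterized as log β for the free
groups, which enforces positivity without constrained optimization.

The likelihood is exact. All 2ᵖ configurations are enumerated (hard limit
p = 20, with an explicit refusal beyond it; the instruments this package
targets have 5–13 items), log Z is computed by log-sum-exp so it stays
finite for |βH| up to the exponential overflow range, and the data enter
only through their sufficient statistics (per-item sums and pairwise
cross-products), so the cost of an objective evaluation is independent of
sample size after one pass over the rows.

Optimization runs L-BFGS-B with the analytic gradient from a deterministic
start (independent-item logistic thresholds, Ω = 0, log β = 0), followed by
Newton polishing with the *analytic* Hessian — exponential-family curvature,
n β² Cov[t(X)] plus the β cross-terms — until the gradient max-norm falls
below 1e-9 per observation (at most 40 Newton steps with backtracking line
search; overall cap 500 iterations). The sharp optimum matters: it is what
makes the saturated fit reproduce empirical cell proportions to 1e-6 and
makes the {−1,+1} and {0,1} fits agree to 1e-8 in fitted probabilities.
Standard errors come from the inverse analytic Hessian at the optimum (the
finite-difference Hessian is kept only as a cross-check in the test suite).
Non-convergence is reported on the fit object and warned about, never
raised; degenerate panels (items with zero endorsements) are the usual
cause.

### Encoding

The primary encoding is {−1,+1}. The {0,1} parameterization of the same
distribution is available through the exact transform ω′ = 4ω,
τ′ᵢ = 2τᵢ − 2Σ_{j≠i} ωᵢⱼ (β unchanged, constants absorbed by Z), and the
estimator is equivariant: fitting relabeled data gives the same β̂ and the
same fitted distributions to numerical precision. Sum-score summaries are
always counted on the {0,1} scale to match questionnaire conventions.

### Sparse structures

Sparse specs are produced by backward stepwise Wald pruning from the dense
fit at the same constraint level: repeatedly drop the single retained edge
with the largest two-sided p-value above `sparse_alpha` (default 0.01,
exposed in config — the pruning rule and level are this package's choice)
and refit. For per-group-edge (saturated) specs the edge statistic combines
groups as a sum of squared z-scores on G degrees of freedom; edges are
otherwise shared, and the retained edge *set* is always common to all
groups. Ties are broken toward the lexicographically smaller (i, j) pair so
runs are deterministic. Pruning everything returns the independence
structure with a warning.

### Model selection

Fit indices follow the structural-equation-modeling convention with the
dense saturated model (0 df) as reference: χ² = 2(ℓ_sat − ℓ_model),
df = k_sat − k_model, AIC = −2ℓ + 2k, BIC = −2ℓ + k ln N, and
RMSEA = sqrt(max(χ² − df, 0)/(df (N − 1))) with N the pooled sample size
(the single-population formula; multigroup √G variants exist, and the
implemented convention is declared here and in output metadata). The grid
crosses the four constraint levels with dense/sparse (eight models; two for
a single occasion, where the β-free levels drop out). The selection rule is
operationalized as *lowest BIC among converged models with RMSEA < 0.05*;
if none passes the RMSEA screen the lowest-BIC model is flagged instead of
silently promoted. The full index table is always returned so users can
apply their own rule. Likelihood-ratio tests between explicitly nested fits
are provided separately.

### Uncertainty

Analytic CIs for T are delta-method intervals on log β (then transformed),
which respects positivity and yields slightly asymmetric intervals. The
bootstrap resamples individuals with replacement *within* each wave — waves
are independent samples in the fitted model class — implemented as
multinomial resampling of each wave's 2ᵖ-state histogram, which is
distributionally identical to row resampling at O(2ᵖ) cost per replicate.
Replicates warm-start from the point estimate, skip standard errors, and
are dropped (and counted, with a warning above 10%) if they fail to
converge. Intervals are 2.5/97.5 percentiles of β̂ and 1/β̂. Seeds are split
per replicate index from one root seed, so results are reproducible and
independent of scheduling.

### Stratified trajectories and the interaction test

Strata (for example sex) are fitted completely independently, each with its
own wave-1 anchoring; outputs therefore carry an explicit note that
cross-stratum curves are *relative cooling rates*, not absolute temperature
differences. The age × stratum test fits temperature ~ age * stratum as a
linear mixed model with a random intercept on the age level, implemented
literally despite the unusual role of age as both fixed effect and grouping
factor; with few age levels the random-intercept variance is frequently
degenerate, in which case the fit reduces to (and is replaced by) ordinary
least squares. Perfectly deterministic inputs (zero residual variance) are
handled explicitly: the interaction p-value is 1 when the coefficient
vanishes. The test consumes point estimates only, mirroring a two-stage
analysis; no weighting by the temperatures' uncertainties is applied by
default.

## Synthetic cohorts

The generator mirrors the model class the estimator targets: a shared edge
matrix, wave-specific thresholds, a β trajectory with β₁ = 1, and
independent waves (no within-person autocorrelation — the estimator fits
cross-sectional models per occasion, so the generator matches that class
rather than a temporal process). Sampling is exact inverse-CDF over the
enumerated state distribution; there are no burn-in or mixing questions at
these scales. MCAR masking is available for exercising the reader's
listwise-deletion path; informative attrition and imputation are out of
scope.

Two stock designs are provided:

- `abcd_like_design`: six items, eight half-yearly waves (ages 10–13.5),
  n = 1,500 per wave, temperature cooling linearly from 1 to 0.6
  (β = 1/T rising). Thresholds relax in proportion to the cooling
  (τ_g = τ_base/β_g) so marginal endorsement stays in a realistic 2–7%
  band while alignment rises — observable symptom rates move modestly even
  as temperature falls substantially, which is exactly the phenomenon a
  stability measure must separate from the marginals.
- `recovery_design`: six items, four annual waves, default
  β = (1, 0.85, 0.70, 0.60) and n = 5,000 per wave, used for the recovery,
  coverage, selection and calibration studies.

Edge weights in both designs span 0.15–0.45 — moderate-to-strong coupling
typical of fitted internalizing-symptom networks — and the recovery
design's per-item thresholds shift by up to ~0.45 between waves, the size
of endorsement-rate changes of roughly 10% → 25% on the logistic scale.
These magnitudes are also what make the recovery questions well posed at
the study sizes: β's information comes entirely through Ω (a near-empty
network leaves β unidentified, which the fitter detects and warns about),
and a dense structure can only be *selected* when every true edge is
individually detectable at the pruning level. Weaker regimes are legitimate
data but turn recovery failures into statements about information, not
about the estimator.

What the generator does not emulate: item-level measurement error beyond
the Ising likelihood itself, within-person dependence across waves,
attrition that correlates with symptom state, and cohort-specific item
content. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the fitted model class, not robustness to those
real-data complications.

## Study sizes and numerical choices

The simulation studies in the test suite use: 50 seeded cohorts at
n = 5,000/wave for β recovery (mean |β̂ − β| per wave) and percentile
bootstrap coverage at B = 200; 50 cohorts at n = 2,000/wave for selection
recovery; 200 two-wave simulations at n = 2,000 for likelihood-ratio
type-I calibration; n = 40,000 draws for sampler moment checks. These sizes
put Monte Carlo noise comfortably inside the asserted bands while keeping
the full suite around five minutes on one CPU. Convergence tolerances:
relative log-likelihood change 1e-12, gradient max-norm 1e-9 per
observation after polishing, enumeration limit p = 20. Numeric CSV output
is written at 10 significant digits.

## Known limitations

- Exact enumeration only: p > 20 is refused rather than approximated.
- Complete-case estimation: missing cells must be dropped (listwise per
  wave) or handled upstream; there is no EM or full-information path.
- Temperatures are relative to the anchored first occasion; levels are not
  comparable across independently anchored fits.
- The mixed-effects interaction test with a handful of age levels usually
  degenerates to OLS; its p-values inherit the usual two-stage caveats.
- Boundary data (zero-endorsement items, empty cells in small panels) can
  push the saturated MLE toward infinite thresholds; such fits are returned
  with the convergence flag down rather than repaired.
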