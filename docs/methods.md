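# Methods

## Model

`addgp` fits an additive Gaussian-process regression to longitudinal data:
one row per (subject, visit), a numeric target y, and typed covariates —
continuous (age, time from a disease event, season), binary (group, gender,
location) and categorical (subject id). The regression function is a sum of
independent GP components

    y = f^(1)(x) + ... + f^(D)(x) + eps,      eps ~ N(0, sigma2_eps),

each component depending on a small covariate subset through its kernel:

| covariate / term    | kernel                                   | free parameters |
|---------------------|------------------------------------------|-----------------|
| age (shared trend)  | squared exponential (se)                 | l, sigma2       |
| season              | periodic, period fixed by the user       | l, sigma2       |
| diseaseAge          | non-stationary se on sigmoid-warped time | l, sigma2       |
| id                  | categorical x constant                   | sigma2          |
| group/gender/loc    | binary x constant                        | sigma2          |
| discrete x age      | (categorical or binary) x se             | l, sigma2       |

Discrete components are products of an indicator kernel with a constant
kernel, so each carries exactly one magnitude. Every component is further
multiplied by binary *mask* kernels built from the missingness flags of the
covariates it touches: any Gram entry involving a missing value is exactly
zero, so missing covariates (e.g. diseaseAge for controls, who have no
disease event) contribute nothing, and no imputation is ever performed.

The non-stationary kernel warps raw time-from-event t (months) through
omega(t) = 2c(-1/2 + 1/(1+exp(-a(t-b)))) with fixed (a, b, c) = (0.5, 0, 40),
concentrating variation in roughly a +/-12-month window around the event;
the warped coordinate is then standardised like any continuous covariate.
Warping the raw months (rather than a standardised time) keeps the window
in interpretable units.

With Gaussian noise the latent functions marginalise analytically; the
marginal likelihood is N(y; 0, K_y) with K_y = sum_j K^(j) + sigma2_eps I,
evaluated by Cholesky factorisation with escalating diagonal jitter
(1e-8 x mean diagonal, escalating tenfold to 1e-4, then abort). Predictions
use the standard conditional-Gaussian equations; a single factorisation per
parameter setting is shared across the D per-component predictions
mu^(j) = K^(j)_{*,X} K_y^{-1} y, whose sum equals the full predictive mean.

## Standardisation and priors

The target and all non-periodic continuous covariates are z-scored (sample
sd over observed entries); periodic covariates keep natural units so the
user-set period stays meaningful, and binary/categorical covariates are not
transformed. Predictions and posterior magnitude summaries are mapped back
to the original target scale through the stored means/sds.

Priors on the standardised scale (all verified to integrate to 1 by
quadrature in the test suite):

- shared continuous length-scales: log-normal(mu = 0,
  sigma2 = (log 1 - log 0.1)^2 / 4); mode ~ 0.27, discouraging length-scales
  below 0.1 (P(l < 0.1) ~ 2.3%);
- interaction length-scales: half Student-t(0, 1, nu = 4), admitting the
  smaller length-scales plausible for subject-level deviations;
- se/periodic magnitudes: square-root Student-t(0, 1, nu = 20) — the square
  root of the variance is half-t with the change-of-variables Jacobian;
- constant-kernel magnitudes (discrete terms): square-root Student-t(0, 1, nu = 4);
- noise variance: scaled inverse chi-squared(sigma2 = 0.01, nu = 1);
- periods and warp constants: fixed, never sampled.

The square-root Student-t is interpreted as a half-t on the *standard
deviation* scale; this is a convention (the parameterisation is not uniquely
pinned down by the name) and is validated indirectly by parameter recovery
on simulated data. Sampling operates on log-parameters, so the
log-posterior adds the exp-transform Jacobian; a parameter with a `fixed`
prior contributes neither density nor Jacobian.

## Inference

**MCMC.** Coordinate-wise univariate slice sampling over independent chains
(default 4 chains, 1000 iterations, 500 burn-in, thinning 2). The generic
path uses stepping-out + shrinkage with width 1 on the log scale and chains
initialised at jittered prior modes; the model-fitting helper used by the
search first computes a Laplace warm start (posterior mode by quasi-Newton,
per-coordinate scales from the finite-difference Hessian) and then runs the
fixed-interval variant of the slice sampler (interval ~ 8 posterior sds,
randomly positioned — also exactly invariant, and cheaper because no
stepping-out evaluations are needed).
Convergence is checked by the split-chain potential scale reduction factor;
if any parameter exceeds 1.1 the run is repeated once with doubled length
and then accepted with a warning. Exactly identical chains give PSRF 1.0 by
construction. All sampling is seed-deterministic, and every child seed in
composite procedures is derived from the master seed keyed by the candidate
model's formula, so results do not depend on execution order.

**CCD.** For the model-comparison loops that refit many times, a
deterministic central composite design replaces MCMC: the posterior mode is
found by quasi-Newton optimisation (finite-difference gradients, up to ten
jittered restarts), curvature comes from the central-difference Hessian
(identity fallback with a warning when it is not negative definite), and a
split-Gaussian is calibrated per whitened half-axis from the log-density
drop at a unit whitened step. Design points are the mode, star points at
+/- f0 sqrt(p) along each whitened half-axis, and two-level factorial
corners on the same shell (full factorial up to p = 5, a resolution-III
fraction above). Because all non-mode points share one whitened radius, the
q(gamma_r) Delta_r mixture weights reduce to the moment-matched rule: the
mode carries 1 - 1/f0^2 and the shell splits the rest evenly. The default
f0 = sqrt(3) makes the one-dimensional design the three-point Gauss-Hermite
rule, so a 1-D Gaussian posterior is integrated exactly; in any dimension
the design reproduces a Gaussian's first two moments.

## Model comparison and search

Candidate models are compared by held-out predictive density. For
continuous covariates, leave-one-row-out densities come from one full-data
MCMC run via Pareto-smoothed importance sampling: the exact per-row
conditionals log p(y_i | y_-i, Theta_s) are computed in closed form from one
factorisation per draw, and the importance ratios are tail-smoothed (the
generalised-Pareto fitting and tail replacement are delegated to
`arviz.psislw`). Rows whose Pareto-k diagnostic exceeds 0.7 — the published
reliability threshold for smoothed importance sampling — are replaced by an
exact single-row refit: a fresh MCMC run by default, or the faster CCD
refit inside the forward search, whose training sets are large enough for
the CCD to be accurate (at very small N the split-Gaussian is a poor match
to the diffuse, skewed hyperparameter posterior, so MCMC is the safer
default). For discrete covariates, stratified
cross-validation leaves out all rows of one subject at a time and refits
with the CCD (warm-started at the full-data mode), scoring the joint block
density under the mixture.

Pointwise densities are turned into comparison probabilities by the
Bayesian bootstrap: Dirichlet(1, ..., 1) weights over the held-out units
(rows or subjects), the probability that the weighted mean log-density
difference is positive (ties count one half, so identical models score
exactly 0.5), with 2000 weight draws by default. With several candidates,
rank probabilities count how often each model attains the best weighted
mean.

The greedy forward search starts from the subject-id base model. Phase 1
adds continuous covariates: each unused covariate proposes the current
model plus its shared term plus the allowed interaction products with
covariates already in the model; the proposals are ranked, and the top one
is accepted when its bootstrap factor over the current model exceeds 0.8.
Phase 2 repeats with discrete covariates under stratified CV and threshold
0.95. Proposals with equal rank are broken by parsimony (fewer parameters,
then declared order); a rejected covariate is not retried within a phase.
Finally the selected model is refit by MCMC, components whose explained
variance falls below 1% are pruned, and the model is refit once after
pruning (the search is not re-run). Explained variance is the variance
over training rows of each component's mixture-mean prediction, normalised
by the sum over components plus the posterior-mean noise variance — a
model-internal normalisation that keeps fractions in [0, 1]; dividing by
the empirical target variance instead would change only small fractions.

## Synthetic data

The generator draws from five known additive structures (AGPM1-5, see
`addgp.simulate`) over a case-control design: by default 40 subjects
(20/20), visits every 3 months from 0 to 36, onset times uniform over the
follow-up for group-1 subjects, loc/gender per-subject Bernoulli(1/2),
shared component variances 4, noise variance 3, length-scales 1 (shared)
and 0.8 (interaction) on the standardised covariates. Interaction
magnitudes are also 4 (a config default; only the shared-component value is
pinned by the study design). Onset times are drawn for group-1 subjects in
every generating model — also in AGPM1-3, where the disease-age component
is absent — so specificity against a *present but irrelevant* diseaseAge
covariate is testable. Components are sampled exactly from their
multivariate normals on the active (unmasked) rows; the disease-age
component is exactly zero on control rows. Group and gender never carry an
effect and act as irrelevant covariates.

What the generator does *not* emulate: measurement-occasion irregularity,
covariate measurement error, non-Gaussian noise, and missing target values.
Passing selection tests on these data therefore demonstrate recovery of
additive GP structure under the stated design, not robustness to those
real-data features.

## Verification scales

The repeated simulate-and-select study and the other stochastic checks run
at reduced designs chosen once for desk-scale verification:

- selection study: 10 replicates per generating model AGPM1-4, 12 subjects
  (6 cases / 6 controls), 6-month visits (7 per subject, N = 84), noise
  variance 3, sampler 2 chains x 400 iterations. Sensitivity to the
  disease-age effect and to the location effect falls with the number of
  cases (the subject-specific age trends can absorb a non-stationary effect
  observed in only a handful of subjects, and the stratified-CV bootstrap
  over few subjects rarely clears the conservative 0.95 threshold), so this
  scale probes far less power than the 20-case design it miniaturises.
- parameter recovery: the true AGPM2 structure fit to draws with 20
  subjects (noise variance 1), 6-month visits.
- null specificity: 10 pure-noise datasets on an 8-subject design with
  6-month visits.
- PSIS-LOO validation: 20 datasets of 10 rows (5 subjects x 2 visits),
  compared against exact per-row MCMC refits.

`scripts/acceptance.py` re-runs a compact version of these analyses from
scratch and writes the headline numbers as JSON.

## Known limitations

- Gaussian likelihood only; no sparse/variational approximations, so cost
  is O(N^3) per likelihood evaluation (practical to roughly N ~ 1000).
- At most one continuous covariate per product term (the normal form used
  by the kernel table above); continuous-continuous interactions are out of
  scope.
- The CCD assumes a roughly unimodal, log-concave posterior; strongly
  multimodal hyperparameter posteriors would need the MCMC route.
- Greedy forward search can miss jointly-relevant covariates that are
  individually weak, and the bootstrap thresholds (0.8 / 0.95) are
  conventions inherited from the study design, not calibrated error rates.
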