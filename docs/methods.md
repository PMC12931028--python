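# Methods

## Model

`stdsurv` fits a parametric proportional-hazards survival model with three
levels of nesting: patients within surgeons within centers. The conditional
hazard for patient $i$ of surgeon $j$ in center $k$ is

$$h_{ijk}(t) = p\,\lambda\,t^{p-1}\exp(X_{ijk}\beta + \alpha_{jk} + \gamma_k),$$

with Weibull baseline shape $p>0$ and scale $\lambda>0$, fixed case-mix
effects $\beta$, and independent normal random intercepts
$\alpha_{jk}\sim N(0,\sigma^2_\alpha)$ (surgeon) and
$\gamma_k\sim N(0,\sigma^2_\gamma)$ (center). Nesting is structural: a
surgeon belongs to exactly one center (validated at load time), and the
two intercepts are uncorrelated by construction. Censoring is assumed
non-informative; follow-up times are treated in whatever unit the data
declares. Left truncation, time-varying covariates and interval censoring
are out of scope, as are crossed random effects and competing risks.

## Estimation

The marginal likelihood of a center integrates its own intercept and its
surgeons' intercepts out of the conditional likelihood. Both integrals are
one-dimensional thanks to conditional independence of surgeons given the
center effect, and are computed by *adaptive* Gauss–Hermite quadrature:
nodes are recentered at the conditional mode and rescaled by the curvature
there. Under the Weibull likelihood a surgeon's conditional log-likelihood
collapses to $C + Du - Be^u$ in the total frailty $u=\alpha+\gamma$ (with
$D$ the surgeon's event count and $B$ its accumulated baseline-hazard
mass), so the inner mode solves a strictly concave scalar equation by
damped Newton iteration, vectorized over all surgeons; the outer (center)
mode is found by a finite-difference Newton search warm-started across
optimizer iterations. Log-sum-exp accumulation keeps everything finite. A
zero variance component collapses its integral to a point mass at zero —
no division by $\sigma$ ever occurs.

Maximization runs on the transformed scale
$(\log p,\log\lambda,\beta,\log\sigma^2_\alpha,\log\sigma^2_\gamma)$ with
L-BFGS-B, started from a cheap single-level Weibull PH fit (variances
started at 0.05). Either variance can be fixed (typically at zero) to fit
degenerate or two-level models. The covariance of the transformed
estimates is the inverse of a central finite-difference Hessian (step
$\max(10^{-4}, 10^{-4}|x|)$ per coordinate); if the Hessian is not
positive definite the covariance is flagged unavailable and the
Monte-Carlo interval machinery refuses to run. Convergence failures are
reported in the results object, never hidden.

Default quadrature uses 15 nodes per level (configurable; oracle tests
confirm 8-digit stability between 15 and 35 nodes, and some large
simulation studies in the test suite use 7 nodes for speed after checking
agreement).

## Empirical-Bayes prediction

With parameters fixed at their MLEs, the joint posterior of a center's
effects factorizes over surgeons given $\gamma$. Posterior means and SDs
are computed from the same nested quadrature (outer rule over $\gamma$
recentered at its posterior mode; inner conditional moments of each
$\alpha_j$), so no multi-dimensional grid is ever built. Posterior means
are the default prediction — they minimize posterior mean-squared error —
with posterior SDs from the quadrature second moment. Posterior modes are
also provided: the joint mode is found by profiling $\gamma$ (each
$\alpha_j$ has a closed Newton update), and SDs come from the inverse of
the arrow-structured joint Hessian at the mode. A cluster with no events
or subjects shrinks to its prior; ranking ties break lexicographically by
cluster id. "Best" means the smallest predicted intercept (lowest hazard).
The location-scale t posterior alternative is a documented hook, not
implemented. How the source analyses computed the SDs of their published
EB predictions is not stated there; posterior SDs are used here and
propagate into the intervals below.

## Standardization

Directly standardized survival fixes the random effect(s) of the profiled
cluster(s) and averages conditional survival
$S_0(t)^{\exp(X\beta+\alpha+\gamma)}$ over a reference population — by
default all $n$ subjects, optionally a center's own patients or any row
subset. Marginalizing one level (e.g. center-specific curves net of
surgeons) integrates that effect over its estimated prior
$N(0,\hat\sigma^2)$ with a non-adaptive 30-node Gauss–Hermite rule (the
integrand is an exactly-Gaussian prior expectation, so adaptivity adds
nothing). The estimated prior — not the empirical bag of EB predictions —
is the chosen reading of the marginal estimands; this is documented
because either convention is defensible. The theoretical-average cluster
sets an effect to zero. Contrasts are pointwise differences of curves and
are only allowed between estimates sharing the same time grid and the same
standardization population, so comparisons always share a case-mix.

Each estimate records the fraction of the standardization population drawn
from other clusters (an extrapolation warning, no automatic trimming).
Default time grid: 100 equally spaced points up to the 99th follow-up
percentile.

Direction of the marginalization effect: $g \mapsto S_0(t)^{\exp(lp+g)}$
is convex in $g$ exactly where the conditional survival falls below
$1/e$ and concave above it, so a marginal curve lies *below* the
fixed-at-prior-mean curve early in follow-up and *above* it late. The test
suite checks both regimes.

## Uncertainty

For any standardized estimand or contrast $\psi$, the package draws $B$
parameter vectors from the multivariate normal approximation on the
transformed scale (back-transformed, so positivity always holds), draws
random-effect values independently per cluster from $N(\text{EB mean},
\text{posterior SD}^2)$, re-evaluates $\psi$, and reports the SE across
repetitions (1/B normalization) and the empirical 2.5th/97.5th percentiles
(default $B=1000$; a normal-approximation interval is optional). The point
estimate is the plug-in value, not the draw mean. Effects fixed at zero
(theoretical-average clusters) carry no posterior uncertainty, so their
draw step is skipped. Parameter and effect draws are independent, matching
the two separate draw steps of the procedure; a joint covariance between
them is not modeled. Non-finite repetitions are dropped with a logged
count; more than 5% aborts. The non-parametric hierarchical bootstrap is
deliberately not implemented (it requires refitting per replicate and
resampling whole clusters); the CLI reserves the flag and explains.

The median hazard ratio summarizing a variance component is
$\exp(\sqrt{2\sigma^2}\,\Phi^{-1}(3/4))$ — the median hazard ratio between
the higher- and lower-risk member of random cluster pairs.

## Synthetic data

The generator draws from exactly the model above: center effects, surgeon
effects, covariates (independent normals/Bernoullis), then event times by
inversion, $T^*=(-\log U/(\lambda e^\eta))^{1/p}$, censored by the minimum
of an administrative horizon and an independent exponential time. One seed
feeds a hierarchical stream split (center, surgeon and per-surgeon subject
substreams), so growing a cluster does not perturb any drawn effect — the
truth table stays fixed across scenario sizes.

`studylike_config()` emulates the motivating bladder-cancer study design:
21 centers, 3 surgeons per center, 20 patients per surgeon (n = 1,260),
covariates age ~ N(65, 10²) with log-hazard slope 0.02/year, sex ~
Bernoulli(0.8) with −0.10, chemotherapy ~ Bernoulli(0.5) with −0.25,
Weibull shape 1.1, intercept variances 0.018 (surgeon) and 0.019 (center),
administrative censoring at 15 time units plus exponential censoring at
rate 0.03. The baseline scale 0.067 places the 10-year survival of an
average patient near 0.08, inside the range of the published standardized
probabilities. These are emulation choices — the original generator's
parameters are not public — so fitted values on any one simulated dataset
recover the generator up to ordinary sampling noise, not the published
estimates digit-for-digit. The generator draws covariates independently of
the random effects and makes censoring non-informative; real provider data
can violate both (differential referral, informative follow-up), so
passing tests here certify the estimators under the model's assumptions,
not robustness to their failure.

## Problem sizes used in the checks

The simulation studies in the test suite use: 50 replicates of a
40-center/160-surgeon/4,000-patient design for parameter recovery, and 200
replicates of a 16-center/640-patient design with $B=500$ for interval
calibration — sizes chosen to sit in the regime where ML asymptotics are
informative while the whole suite stays quick. The acceptance script runs
the full n = 1,260 study-like pipeline with $B=1000$.

## Known limitations

- Maximum likelihood estimates the top-level variance with a downward
  finite-sample bias when the number of centers is modest (of order
  $1/K$ and beyond). With 40 centers the recovery study measures a mean
  $\hat\sigma^2_\gamma \approx 0.087$ against a generating 0.10, and an
  independent ML implementation reproduces the same shortfall on the same
  datasets, so this is a property of the estimator, not of the
  implementation. REML-type corrections are not provided.
- Hessian-based parameter covariances are asymptotic; with very few
  clusters (≈8 centers) the implied intervals undercover by several
  points. Interval calibration is demonstrated at 16+ centers.
- Variance components estimated at the boundary ($\hat\sigma^2\to 0$)
  leave the corresponding covariance entry ill-determined; the results
  object flags the covariance rather than guessing.
- The random-effect draws in the interval machinery ignore the (typically
  small) posterior correlation between clusters and between effects and
  parameters.
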