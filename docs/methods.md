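# Methods

## The estimation problem

In a cluster-randomized trial (CRT) with nontrivial mortality, a
nonmortality outcome such as quality of life is *truncated by death*: it is
undefined, not merely unobserved, for participants who die before
measurement. Comparing survivors between arms has no causal interpretation,
because treatment can change who survives. The estimand with a clean
interpretation is the survivor average causal effect (SACE),

    delta = E[ Y(1) - Y(0) | G = 11 ],

the mean difference of counterfactual outcomes restricted to
*always-survivors* — participants who would survive under either
assignment. `crtsace` implements a Bayesian joint model that identifies the
latent always-survivor stratum and estimates the SACE while accounting for
the intracluster correlation that cluster-level randomization induces.

## Model

**Principal strata.** Each participant belongs to one of three latent
strata defined by the pair of potential survival statuses: never-survivor
(`00`), protected (`10`, survives only if treated), always-survivor
(`11`). The harmed stratum is excluded by the monotonicity assumption
(treatment does not worsen survival). Membership follows a multinomial
logistic model on baseline covariates `x` (intercept first) with
always-survivors as the reference:

    P(G=00) ∝ exp(x'beta),   P(G=10) ∝ exp(x'gamma),   P(G=11) ∝ 1.

Optionally a cluster random intercept `chi_i ~ N(0, phi2)` is added to both
non-reference predictors (a single shared deviation, keeping one variance
parameter). A latent-scale intracluster correlation `icc` maps to
`phi2 = icc/(1-icc) * pi^2/3` through the logistic latent variance.

**Outcomes.** Only three stratum-by-arm cells carry an observable outcome:
always-survivors in either arm and protected participants under treatment.
Each cell has its own coefficient vector (`alpha_11_1`, `alpha_11_0`,
`alpha_10_1`) but all three share one cluster random effect
`eta_i ~ N(0, tau2)` and one residual variance `sigma2`:

    Y_ij(d) | G, i  ~  N( x_ij' alpha_{G,d} + eta_i, sigma2 ).

The outcome intracluster correlation is `rho = tau2 / (tau2 + sigma2)`.

**Observed-data structure under monotonicity.** Treated deaths are
never-survivors and control survivors are always-survivors; treated
survivors are a two-component mixture (always/protected), control deaths a
two-component mixture (protected/never) whose outcome is truncated.

## Priors

The default analysis uses diffuse proper priors; the hyperparameters are
configurable and default to

- every regression coefficient (outcome and strata models): `N(0, 1e4)`;
- `sigma2`, `tau2`, `phi2`: `InvGamma(0.01, 0.01)`.

These defaults are this package's choice and follow the common
noninformative convention for conjugate mixed models. Proper (if diffuse) normal priors are placed on
`beta` and `gamma` as well, which keeps the Metropolis target integrable.

## Posterior computation

Each MCMC iteration performs, in order:

0. *Pairing-swap move.* A collapsed Metropolis step proposes exchanging
   `alpha_11_1` with `alpha_10_1`, with the treated survivors' latent
   labels integrated out analytically (each row contributes
   `p11(x) N(y|x'a+eta) + p10(x) N(y|x'b+eta)`). The swap is a symmetric
   involution and the coefficient priors cancel, so the acceptance ratio
   is the product of row-wise mixture-likelihood ratios. See "Why the
   swap move" below.
1. *Membership augmentation.* Deterministic cells are set; treated
   survivors draw always-vs-protected from the product of membership
   probability and outcome density; control deaths draw
   protected-vs-never from membership probabilities alone (their outcome
   is truncated, so no likelihood term exists). Together with step 0 this
   is a valid partially collapsed update: the labels marginalized in the
   swap are redrawn from their exact conditional immediately after.
2. *Outcome coefficients* by conjugate Gibbs per cell: multivariate normal
   with precision `X'X/sigma2 + I/v0`. Empty cells draw from the prior so
   the chain stays irreducible.
3. *Cluster effects* by conjugate Gibbs:
   `N( (R_i/sigma2)/(k_i/sigma2 + 1/tau2), 1/(k_i/sigma2 + 1/tau2) )`.
4. *Variances* by inverse-gamma Gibbs.
5. *Strata coefficients* by blocked random-walk Metropolis (`beta` then
   `gamma`) with multivariate-t proposals, `t_df = 4` (heavy tails,
   finite variance). Optionally, per-cluster scalar random-walk updates
   for `chi_i` (the target factorizes over clusters, so all clusters are
   proposed and accepted independently in one vectorized pass), followed
   by an inverse-gamma draw for `phi2`.
6. *Estimand recording* (retained iterations only): the SACE draw is the
   mean of `x'(alpha_11_1 - alpha_11_0)` over rows currently labeled
   always-survivor — the cluster effects cancel in the difference, and
   this Rao-Blackwellized form has the same posterior mean as
   posterior-predictive differencing with much lower Monte-Carlo
   variance. Stratum proportions, the outcome ICC, and the
   always-survivor covariate profile are recorded from the same state.

**Adaptive proposals.** Proposal scale matrices start at
`T0 = 6 (X'X)^{-1}` (a logistic-information heuristic that puts the
initial step size near the posterior scale) with the Gelman–Roberts–Gilks
factor `s = 2.38^2/p`. From iteration 200, every 100 iterations during
burn-in, `T` is replaced by the empirical covariance of the second half of
the chain history (discarding the initialization transient) plus a `1e-6`
ridge, and `s` is multiplied by `exp(accept_rate - 0.234)`. A degenerate
(zero-variance) history leaves `T` unchanged and halves `s`, which
rescues a chain whose proposals are far too large to ever accept.
Adaptation freezes at the end of burn-in so the retained chain is Markov.

**Initialization.** Arm-level survival rates moment-match the initial
stratum shares: control-arm survival estimates the always-survivor share,
the treated-minus-control difference the protected share. Ambiguous
memberships are drawn at those odds, the strata-model intercepts start at
the corresponding log-odds, outcome coefficients at per-cell least squares
(with `N(0, 0.01^2)` jitter), and variances at residual moments. All
randomness flows from the run seed, so runs are exactly reproducible.
A uniform split of the ambiguous memberships was tried first and abandoned:
it starts the protected-treated regression on a half-wrong mixture and
makes the crossed-pairing trap (below) more frequent.

**Why the swap move.** The treated-survivor mixture admits a spurious,
locally stable posterior mode in which the two treated-arm regressions
exchange subpopulations (each fitting mostly the other stratum's members).
With the outcome residual sd (sqrt(5) ≈ 2.24 under the reference
conditions) large relative to the component separation, plain
augmentation can take thousands of iterations to escape; desk-scale
chains that commit to the crossed pairing produce SACE draws with the
wrong sign. The collapsed swap directly compares the two pairings'
marginal likelihoods each iteration, so a chain in the crossed mode
switches as soon as the dominant pairing fits better, at negligible cost
(one extra mixture-likelihood evaluation per iteration).

**Diagnostics.** Multi-chain runs report rank-normalized split-R-hat (via
`arviz`) for every scalar parameter and per-chain Metropolis acceptance
rates; tuned acceptance typically lands in 0.10–0.35.

## Synthetic-data generator

`generate_crt` emulates a two-arm CRT with truncation by death and known
ground truth. Reference conditions (the generator defaults):

| quantity | value |
| --- | --- |
| cluster size × clusters | 15 × 100 (1,500 participants) |
| allocation | 1:1 at the cluster level |
| covariates | X1 ~ Normal(0, variance 4), X2 ~ Uniform(−5, 5) |
| membership coefficients | beta = (−1, 0.3, 0.5), gamma = (−0.8, 0.6, 0.4) |
| outcome coefficients | alpha_11_1 = (1.5, 0.5, 0.8), alpha_11_0 = (0.2, 0.3, 0.6), alpha_10_1 = (−1.5, 0.9, 0.5) |
| variances | sigma2 = 5, tau2 = 1 (outcome ICC = 1/6 ≈ 0.167) |

These induce marginal stratum shares of ≈ 21.1% / 26.5% / 52.4%
(never / protected / always). "Normal(0, 4)" is read as variance 4
(standard deviation 2); a Monte-Carlo check of the induced shares against
those percentages supports this reading. Variable cluster sizes use a
gamma distribution with mean `m` and sd `cv·m`, rounded and floored at 2
(no degenerate singleton clusters); `cv` is the conventional
sd(size)/mean(size). An optional membership-model cluster intercept is
generated from the latent-scale ICC.

What the generator does **not** emulate: informative cluster size,
non-normal or heteroscedastic outcomes, covariate-dependent truncation
beyond the stratum mechanism, missing covariates, or the covariate
structure of any particular real trial. Passing recovery tests therefore
demonstrate correctness of the estimator *under its own assumptions*, not
robustness to their violation.

**Truth oracle.** The true SACE of a configuration is
`E[x'(alpha_11_1 - alpha_11_0) | G = 11]`, estimated by direct simulation
of (x, G) at 1e6 draws (standard error < 0.01, typically ≈ 0.0008). Under
the reference conditions the truth is ≈ 0.92: selection through the
covariate terms pulls the SACE below the intercept contrast of 1.3,
because always-survivors have below-average X1 and X2. The oracle value —
not any externally printed constant — is the reference for all recovery
scoring.

## Recovery study (operating characteristics)

`run_recovery_study` generates `reps` trials (seeds `seed + r`), fits each
with a single chain, and reports per parameter: truth, mean posterior
mean, percent relative bias, 95% credible-interval coverage, and the
Monte-Carlo standard error. Defaults: 50 replicates at the reference
conditions, each fitted with the full per-trial protocol of 10,000
iterations and 2,500 burn-in — about nine minutes on one CPU with the
vectorized sampler. Shorter fits were examined and rejected as defaults:
at 2,000 iterations a nontrivial fraction of chains is still near the
crossed pairing when burn-in ends, inflating the SACE bias by several
points. Larger replications (e.g. 200 replicates) run through the same
interface.

With 50 replicates, coverage of a nominal-95% interval has a binomial
standard error of ≈ 3–4%, so observed coverages from the high 80s to 100%
are consistent with nominal; single-seed coverage numbers should be read
with that noise in mind.

## Numerical policy and edge cases

- All membership probabilities are computed on the log scale with
  max-subtraction; linear predictors up to |700| do not overflow.
  Probabilities are floored at 1e-300 before logging.
- If both components of a treated survivor's augmentation posterior
  underflow, the membership probabilities alone decide and a warning is
  logged (in log space this requires a pathological state).
- Draws with an empty always-survivor set are flagged, counted, and
  excluded from SACE summaries.
- Clusters with no observed-outcome rows draw their random effect from
  `N(0, tau2)`; empty outcome cells draw coefficients from the prior.
- A size-1 cluster combined with the clustered membership model triggers a
  warning recommending the unclustered model (with singleton clusters the
  per-cluster intercept is weakly identified and the model tends not to
  converge).
- Credible intervals are 2.5/97.5 empirical percentiles with linear
  interpolation; the point estimate is the posterior mean.

## Comparator

`complete_case_lmm` fits the analysis a practitioner might default to — a
linear mixed model of the outcome on treatment and covariates among
survivors only (via `statsmodels` MixedLM, REML). It is reported alongside
the SACE for contrast only: under truncation by death it mixes principal
strata and has no causal interpretation.

## Known limitations

- Monotonicity is assumed, not tested; trials where treatment may harm
  survival need a different identification strategy.
- The always-survivor counterfactual means are defined over each draw's
  finite always-survivor set; they are in-sample quantities, not
  super-population functionals.
- The nested-probit membership model, repeated measures, informative ICC
  priors, and frequentist cluster-robust variances are out of scope.
- Very small trials (fewer than ~20 clusters) were not validated here and
  small-sample behavior of the diffuse variance priors can be material.
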