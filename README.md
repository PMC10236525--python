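# crtsace

Bayesian estimation of the **survivor average causal effect (SACE)** in
**cluster-randomized trials (CRTs)** whose nonmortality outcome (e.g.
quality of life) is **truncated by death**.

## The problem

When a sizeable share of trial participants die before the outcome is
measured, the outcome is undefined — not just missing — for them, and a
comparison among survivors mixes systematically different people across
arms. Principal stratification resolves this: classify participants by
their pair of potential survival statuses — always-survivors, protected
(survive only if treated), never-survivors (the harmed stratum is excluded
by monotonicity) — and target the treatment effect where both
counterfactual outcomes exist:

    delta = E[ Y(1) − Y(0) | always-survivor ].

Membership is latent for treated survivors and control deaths, so the
package fits a joint Bayesian mixture: a multinomial-logistic membership
model on baseline covariates and per-(stratum, arm) linear mixed outcome
models sharing a cluster random effect (intracluster correlation
`rho = tau2/(tau2 + sigma2)`), estimated by a custom MCMC — latent-label
data augmentation, conjugate Gibbs steps, and adaptive random-walk
Metropolis with multivariate-t proposals for the membership coefficients.
A synthetic-CRT generator with known ground truth and a bias/coverage
harness reproduce the estimator's operating characteristics at desk scale.
See `docs/methods.md` for the model, algorithm, and design choices.

Audience: biostatisticians analyzing CRTs (or multicenter trials) in
populations with nontrivial mortality, and methodologists studying
truncation-by-death estimands.

## Worked example

Simulate a 1,500-participant CRT (100 clusters of 15) under the package's
reference conditions and fit it:

```bash
crtsace simulate --seed 4 --out trial.csv
# {"rows": 1500, "clusters": 100, "treated_clusters": 50,
#  "true_sace": 0.9232, "true_sace_se": 0.0018,
#  "strata_props": [0.2267, 0.2573, 0.516]}

crtsace fit trial.csv --out-dir results/
```

The fit (two chains of 10,000 iterations, 2,500 burn-in, by default)
prints the posterior summary table (point = posterior mean, interval =
2.5/97.5 percentiles):

```
         estimand     point     lower     upper
             SACE  1.055849  0.489064  1.611112
            Ybar1  0.463148  0.110758  0.813781
            Ybar0 -0.592701 -0.905017 -0.285198
       prop_never  0.226738  0.209333  0.244667
   prop_protected  0.236185  0.206000  0.266667
      prop_always  0.537077  0.518667  0.554667
              ICC  0.193059  0.125840  0.268397
complete_case_lmm  0.306592 -0.216140  0.829325
```

Reading it: among always-survivors (~54% of participants) the treatment
raises the outcome by ≈ 1.06 (95% CrI 0.49–1.61); the generating truth for
this configuration is ≈ 0.92. The outcome ICC posterior brackets the true
1/6. The complete-case mixed model — the analysis one might run instead —
gives 0.31 here and carries no causal interpretation, since surviving
treated participants mix always-survivors with protected individuals.

The same objects are available as a library:

```python
from crtsace import SimConfig, RunConfig, generate_crt, fit_dataset

dataset, truth = generate_crt(SimConfig(seed=4))
result = fit_dataset(dataset, RunConfig(iterations=10_000, burn_in=2_500))
print(result.summary)
```

And the operating-characteristics harness:

```bash
crtsace recover --reps 50 --seed 0 --out recovery.csv
```

which reports, per parameter (SACE, ICC, each regression coefficient,
stratum proportions): truth, average posterior mean, percent relative
bias, and 95% credible-interval coverage across replicated trials.

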