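# bcnma — Bayesian component network meta-analysis

Complex interventions — psychotherapies, multi-faceted care programmes —
are built from elementary **components** (e.g. psychoeducation, behavioural
activation, a waiting-list control), and trials compare **combinations** of
them. Standard network meta-analysis (NMA) treats every distinct
combination as an unrelated treatment, wasting the shared structure.
Component NMA (CNMA) instead models the relative effect of a combination as
the sum of its components' effects, optionally plus pairwise interactions:

    y_i   ~ N(delta_i, s_i^2)                 (study i's observed contrast)
    delta_i ~ N(theta_Y - theta_X, tau^2)     (random effects, SD tau)
    theta_X = sum_{q in X} d_q + sum_{(p,q) in X} d_{p.q}

with multivariate-normal random effects (off-diagonal `tau^2/2`) for
multi-arm trials, and binomial-logit or normal arm-level likelihoods when
per-arm summaries rather than contrasts are reported.

Which interactions `d_{p.q}` to allow is the hard modelling question this
package addresses with two Bayesian shrinkage routes:

- **SSVS (spike and slab):** `d_{p.q} | I_{p.q} ~ (1-I) N(0, eta^2) +
  I N(0, g^2 eta^2)` with Bernoulli inclusion indicators `I_{p.q}` updated
  by Gibbs sampling inside the MCMC. The posterior mean of `I_{p.q}` is the
  interaction's inclusion frequency; expert opinion enters as per-pair
  prior inclusion probabilities.
- **Bayesian LASSO:** a Laplace prior `pi(d_{p.q}) = (lambda/2)
  exp(-lambda |d_{p.q}|)`, sampled through its normal scale-mixture
  representation, with `1/lambda ~ U(0, 5)` by default.

A one-stage joint model pools aggregate studies with individual-patient
data (IPD): patient outcomes get study intercepts `alpha_i`, prognostic
coefficients `beta`, and per-component effect-modification vectors
`gamma_q`, so relative effects between any two combinations can be
predicted for a new patient's covariate profile. Effect modification can
itself be shrunk (SSVS or a conditional Laplace prior, which requires a
common residual SD across IPD studies). Pre-imputed covariate stacks are
fitted per imputation and the posterior draws mixed.

Everything is verifiable without external data: a synthetic-data module
generates networks with known component effects, interactions,
heterogeneity and covariate structure, and the test suite recovers them.

## Worked example

Simulate the reference scenario (6 components a–f, 45 studies, tau = 0.3,
one true interaction d_{a.b} = 1.0), fit the SSVS interaction model, and
summarize:

```python
from bcnma import (ADModelSpec, default_plan, fit_ad, relative_effect,
                   simulate_ad, ssvs_inclusion_summary, summarize)
from bcnma.design import all_pairs
from bcnma.mcmc import MCMCSettings

truth = default_plan()
data = simulate_ad(truth, seed=7)
spec = ADModelSpec(interaction_mode="ssvs", interactions=all_pairs(data.catalog))
draws = fit_ad(data, spec, MCMCSettings(seed=1, chains=2, iterations=2000,
                                        burnin=1000))
print(summarize(draws).head(7))
print(ssvs_inclusion_summary(draws).nlargest(3, "inclusion_frequency"))
print(relative_effect(draws, "a + b", "c"))
```

Output (abridged):

```
parameter    mean  median      sd  ci_low  ci_high    rhat     ess
     d[a]  -0.539  -0.570   0.309  -1.065    0.213   1.023 193.715
     d[b]   0.492   0.456   0.249   0.118    1.184   1.016 215.701
     ...
      tau   0.326   0.325   0.066   0.198    0.478   1.001 709.726

pair  inclusion_frequency  posterior_mean
 a.b                0.936           0.905
 d.f                0.582          -0.049
 b.d                0.561           0.105

(a + b) vs (c): MD 1.25 [0.82; 1.65]
```

The generating truth had `d_a = -0.8`, `d_b = 0.5`, `tau = 0.3` and a 1.0
interaction between a and b: the true pair is selected in 94% of MCMC
iterations with coefficient 0.91, every null pair sits near its 0.5 prior
with a coefficient near zero (the V-shaped selection pattern), and the
(a + b) vs (c) contrast covers its true value of 1.0. Mean and median are
both reported; the credible interval is the equal-tailed 2.5/97.5%
posterior interval.

The same analyses run from the shell:

```sh
bcnma simulate --plan default --seed 7 --out data/
bcnma check    --catalog data/catalog.csv --ad-contrast data/ad_contrast.csv
bcnma fit      --model ssvs --catalog data/catalog.csv \
               --ad-contrast data/ad_contrast.csv --seed 1 --out fit/
bcnma predict  --draws fit/ --compare "a + b" "c"
```

`bcnma fit-ipd` fits the joint AD+IPD model (an `imputation` column in the
IPD CSV triggers per-imputation fits and draw mixing); `bcnma check`
reports network connectivity and which parameter directions are
inestimable (null-space of the stacked contrast design), which the fitters
keep but flag as prior-driven.

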