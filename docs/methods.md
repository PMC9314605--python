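# Methods

## Model family

All models share a two-level core. At the top, study-specific relative
effects `delta_i` are exchangeable around the structural contrast implied
by the arms' component composition:

    delta_i ~ MVN(X_i d, tau^2 P),   P = 0.5 I + 0.5 J,

where `X_i` stacks one signed design row per non-reference arm (entry +1
for a component in the arm only, -1 for the reference only, 0 otherwise;
interaction columns analogous on pair membership) and `P` is the
exchangeable multi-arm correlation structure — every pairwise contrast has
variance `tau^2`, off-diagonal `tau^2/2` — the standard consistency-
preserving NMA convention. Treatment-level (non-component) analysis is the
same machinery after recoding each distinct combination as its own
singleton pseudo-component.

The bottom level depends on the evidence type:

- **Contrast-level AD**: `y_i ~ MVN(delta_i, S_i)`. For multi-arm studies
  the contrasts share the reference arm; `S_i`'s off-diagonal is the
  reference-arm variance when the user supplies it, otherwise the
  equal-split approximation `cov_jk = se_j se_k / 2` (always positive
  definite). This default is an approximation and is noted in the fit
  metadata.
- **Arm-level AD**: binomial counts with a logit link
  (`logit p_ik = mu_i + delta_ik`) or normal arm means with known
  `sd^2/n`. The binomial likelihood needs no continuity correction for
  zero cells.
- **IPD**: `y_ik ~ N(m_ik, sigma_i^2)` with
  `m_ik = alpha_i + beta' x_ik + (sum_{q in t} gamma_q - sum_{q in ref}
  gamma_q)' x_ik + delta_i[arm]`; Bernoulli-logit for a binary outcome.
  `beta` and `gamma` are common across studies. The IPD studies' `delta_i`
  enter the same second level as the AD studies', pooling conditional and
  marginal estimates as exchangeable. The AD part can optionally be
  adjusted by study-mean covariates, `y_i ~ N(delta_i + beta' xbar_i,
  s_i^2)`.

Covariates are centered at the pooled mean over IPD patients (AD study
means are shifted by the same constants; with no IPD, the mean of the AD
study means is used). Centering makes `d` the contrast at the average
patient and makes conditional estimates at the covariate mean coincide
with the unconditional combination contrasts exactly. The centering
constants are stored with the dataset and reapplied to prediction
profiles.

Conventions chosen where the model needed one (results are invariant to
them, fixing them makes runs reproducible): the reference arm of a
contrast-level study is its first listed arm; the reference arm of an IPD
study is the arm earliest in canonical (catalog-ordered) combination
order; combination strings and design columns always follow catalog order.

## Priors and defaults

| parameter | default prior | notes |
|---|---|---|
| component effects `d_q` | N(0, 10^2) | vague on MD / log-OR scales |
| study baselines `mu_i`, `alpha_i` | N(0, 10^2) | |
| heterogeneity `tau^2` | LN(-1.67, 1.472^2) | empirically informed default for log-OR outcomes; half-normal `N(0,10^2)I(0,)` and uniform alternatives |
| free pair terms (interaction mode "full") | N(0, 10^2) | `d_pair_sd` configurable |
| SSVS spike scale `eta` | half-N(0, 0.1^2), i.e. random | a scale cannot be negative, so the narrow zero-centered prior is truncated at 0; fixed-`eta` variant available |
| SSVS slab factor `g` | 100 | slab SD = `g * eta` |
| SSVS inclusion `I_{p.q}` | Bernoulli(0.5) | per-pair informative values and hard exclusions supported |
| LASSO rate `lambda` | `1/lambda ~ U(0, 5)` | half-normal-on-`1/lambda` sensitivity alternative; fixed `lambda` for grids |
| prognostic `beta`, effect modification `gamma` | N(0, 10^2) | gamma optionally SSVS- or Laplace-shrunk |
| within-study SD `sigma_i` | half-N(0, 10^2) | per-study or common |

The conditional Laplace prior on `gamma` supports two exponent
conventions, selected explicitly: the default writes the exponent as
`-lambda |gamma_k| / sigma^2` with normalizer `lambda/(2 sigma)` (this
form's one-coordinate integral is `sigma`, not 1 — it is used as stated,
including its prefactor, in the `lambda` and `sigma` updates); the
`park-casella` convention uses `-lambda |gamma_k| / sigma`, a proper
Laplace density with scale `sigma/lambda`. Both require the common-sigma
model, and the choice is a config switch rather than a silent default
because the two lead to different amounts of shrinkage. The conditional
prior's coupling to `sigma` is what keeps the coefficient posteriors
unimodal.

## Sampling

No probabilistic-programming backend is used; the sampler is
purpose-built:

- `d` (mains + pairs): conjugate multivariate-normal Gibbs update. For
  contrast-level data the study random effects are marginalized
  (`y_i ~ MVN(X_i d, S_i + tau^2 P)`), which removes the funnel between
  `delta` and `tau`; for arm-level and IPD data, latent `delta_i` are kept
  and updated conjugately (normal likelihoods) or by adaptive
  Metropolis (binomial/Bernoulli).
- SSVS indicators: exact Gibbs via the slab/spike density ratio.
- LASSO local scales: inverse-Gaussian Gibbs from the Laplace
  scale-mixture; `lambda`: adaptive MH under its hyperprior.
- `tau`, `eta`, `lambda`, `sigma`: random-walk MH on the log scale with
  Robbins-Monro adaptation toward 0.44 acceptance during burn-in only
  (the kept chain is time-homogeneous).
- IPD fixed effects: conjugate blocks for `alpha_i`, `beta`, and normal-
  prior `gamma`; coordinatewise adaptive MH for Laplace-prior `gamma` and
  for all coefficients under a binary outcome.

Chains are independent streams spawned from the mandatory seed
(`numpy.random.SeedSequence`), so runs reproduce bit-for-bit. Split-R-hat
and arviz bulk ESS are attached to every fit; a warning flag is set when
any monitored R-hat exceeds 1.01. Reference defaults are 4 chains of
30 000 kept iterations after 10 000 burn-in; the test suite and acceptance
script use 1–2 chains of 1 000–4 000 kept iterations, which the
diagnostics show to be ample at the synthetic problem sizes (45 studies, 6
components, 15 candidate pairs; 10–14 studies in the joint scenarios).

## Estimability

Whether individual `d` are identified is a property of the stacked
contrast design: its numerical rank is computed by SVD with singular
values below `1e-8 × s_max` treated as zero (entries are 0/±1, so the
scale is benign; an exact rational-rank oracle cross-checks this in the
tests). The null-space basis is reported with component/pair labels, and
query contrasts are classified by the residual of their projection onto
the row space — any comparison actually made within a study is estimable
by construction, even when single components are not (e.g. two components
always co-administered, or a component present in all arms of every study
that has it). Inestimable directions are reported and retained, not
dropped: the Bayesian priors regularize them, and the fit carries a
warning that those posteriors equal their priors. Automatic recoding or
merging of components to restore identifiability is out of scope.

## Synthetic data

The generator inverts the model likelihoods, so fits of the generating
model are unbiased by construction and recovery failures indicate sampler
or design errors. The reference AD scenario: 6 components, a pool of 10
combinations (all singletons plus a+b, a+b+c, c+d, b+e), 40 two-arm and 5
three-arm studies with arms drawn without replacement from the pool,
contrast SEs uniform on (0.2, 0.4) (the precision of a ~100-patient-arm
binary trial on the log-OR scale), `tau = 0.3`, component effects between
-0.8 and 0.5, and one true interaction `d_{a.b} = 1.0`. The joint
scenario adds 4 two-arm IPD studies of 60 patients per arm with two
standard-normal and one Bernoulli(0.5) covariate (a severity/age/gender-
style mix), prognostic effects up to 0.8 SD and effect-modification
coefficients up to 0.5.

What the generator does *not* emulate — and hence what passing recovery
tests cannot show about real data: non-normal random effects, correlation
between effect size and precision (small-study effects), systematically
missing covariates (inputs are assumed pre-imputed; only draw mixing is
implemented), inconsistency between direct and indirect evidence beyond
what `tau` absorbs, and within- vs across-study separation of
covariate-component interactions.

One deliberate property of the reference scenario: because the true
interaction is large (1.0), the purely additive model fitted to it is
misspecified, and its component estimates for a and b are biased by
several posterior SDs while `tau` inflates (≈0.43 vs 0.3). Additive-model
recovery is therefore verified on the additive variant of the scenario
(interaction coefficient zero), and the interaction scenario is used to
verify that the shrinkage models both recover the truth and *detect* the
interaction. The bias of the additive fit under interaction truth is the
motivating phenomenon for the selection models, not a defect.

## Numerical choices

- Rank tolerance `1e-8` relative; estimability residual threshold `1e-6`.
- Multi-arm contrast covariance default: correlation-1/2 equal-split
  approximation (above); an explicit reference-arm SE overrides it.
- LASSO inverse-Gaussian draws guard `|d|` below `1e-8` to avoid division
  blow-up at the spike.
- Zero cells in binomial arms are handled by the likelihood itself; logit
  probabilities are clipped at `1e-12` for log-safety.
- Adaptive MH proposal scales are clipped to `e^(-10), e^5`.
- Degenerate (zero-variance) draw series report R-hat 1 and full ESS.

## Known limitations

- Contrast-level multi-arm correlation is approximate unless the
  reference-arm SE is supplied.
- The binary-outcome IPD path uses coordinatewise MH and mixes more slowly
  than the conjugate continuous path; it is sized for moderate networks.
- Two-stage IPD meta-analysis, random effects on `beta`/`gamma`,
  exchangeable component effects, Q/DIC-based model comparison, ranking
  metrics, and consistency testing are out of scope.
- Higher-order (3+-way) interactions are accepted through the design
  machinery but undocumented in outputs; estimating them is rarely
  feasible.
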