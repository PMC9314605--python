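"""Aggregate-data CNMA models and their samplers.

The model hierarchy, for a study i contrasting arms against its reference:

    contrast level:   y_i ~ N(delta_i, S_i)
    random effects:   delta_i ~ MVN(X_i d, tau^2 P)
    arm level:        r_ik ~ Bin(n_ik, expit(mu_i + delta_ik))        (binary)
                      ybar_ik ~ N(mu_i + delta_ik, sd_ik^2 / n_ik)    (continuous)

where X_i stacks signed component (and optional pair) design rows and P is
the exchangeable multi-arm correlation structure with unit diagonal and 1/2
off-diagonal, which preserves consistency of the random effects.  At the
treatment level each distinct combination gets its own column instead
(standard NMA).  Interaction coefficients can be left free ("full"), given
a spike-and-slab prior with Gibbs-updated inclusion indicators ("ssvs"), or
a Laplace prior sampled through its normal scale-mixture representation
("lasso").

Sampling is conjugate Gibbs for d (the contrast-level likelihood is
marginalized over delta), Gibbs for indicators and LASSO local scales, and
adaptive Metropolis for tau, eta, lambda and the arm-level baselines and
random effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .datamodel import (
    ADArmStudy,
    ADContrastStudy,
    ComponentCatalog,
    DataError,
    NetworkDataset,
    TreatmentCombination,
)
from .design import CombinationMatrix, InteractionSet, build_design
from .mcmc import (
    AdaptiveScale,
    MCMCSettings,
    PosteriorDraws,
    sample_inverse_gaussian,
    sample_mvn_from_precision,
    split_rhat,
)
from .priors import PriorConfig, indicator_full_conditional

__all__ = [
    "ADModelSpec",
    "PosteriorDraws",
    "multiarm_re_covariance",
    "loglik_ad",
    "fit_ad",
    "ssvs_inclusion_summary",
    "treatment_level_dataset",
]

INTERACTION_MODES = ("none", "full", "ssvs", "lasso")
LIKELIHOODS = ("contrast-normal", "arm-binomial-logit", "arm-normal")


@dataclass(frozen=True)
class ADModelSpec:
    """What to fit: component vs treatment level, interaction handling,
    likelihood, priors, and the admitted interaction pairs."""

    level: str = "component"  # component | treatment
    interaction_mode: str = "none"
    likelihood: str = "contrast-normal"
    priors: PriorConfig = field(default_factory=PriorConfig)
    interactions: InteractionSet = field(default_factory=InteractionSet)
    fixed_lambda: float | None = None  # overrides priors.lasso when set

    def __post_init__(self):
        if self.level not in ("component", "treatment"):
            raise DataError(f"unknown level {self.level!r}")
        if self.interaction_mode not in INTERACTION_MODES:
            raise DataError(f"unknown interaction mode {self.interaction_mode!r}")
        if self.likelihood not in LIKELIHOODS:
            raise DataError(f"unknown likelihood {self.likelihood!r}")
        if self.interaction_mode != "none" and self.level != "component":
            raise DataError("interaction modes require component-level analysis")


def multiarm_re_covariance(tau2: float, k_arms: int) -> np.ndarray:
    """Random-effects covariance of the k-1 contrasts of a k-arm study.

    Exchangeable structure: tau^2 on the diagonal, tau^2/2 off-diagonal.
    This is the standard NMA convention; it makes every pairwise contrast
    have variance tau^2 and keeps the random effects consistent.
    """
    if k_arms < 2:
        raise ValueError("a study needs at least 2 arms")
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    m = k_arms - 1
    return tau2 * (0.5 * np.eye(m) + 0.5 * np.ones((m, m)))


def treatment_level_dataset(dataset: NetworkDataset) -> NetworkDataset:
    """Recode each distinct combination as its own singleton pseudo-component.

    Fitting the component-level machinery on the recoded data is exactly the
    standard treatment-level NMA: the design matrix has one column per
    distinct combination.
    """
    combos = dataset.all_combinations()
    cat = dataset.catalog
    code_of = {
        c.canonical(cat): c.canonical(cat).replace(" + ", "&") for c in combos
    }
    new_cat = ComponentCatalog(tuple(code_of[c.canonical(cat)] for c in combos))
    remap = {
        c.canonical(cat): TreatmentCombination(frozenset([code_of[c.canonical(cat)]]))
        for c in combos
    }

    def r(combo: TreatmentCombination) -> TreatmentCombination:
        return remap[combo.canonical(cat)]

    ad_contrast = [
        ADContrastStudy(
            st.study_id,
            [(r(c), y, se) for c, y, se in st.arms],
            scale=st.scale,
            ref_se=st.ref_se,
            covariate_means=st.covariate_means,
        )
        for st in dataset.ad_contrast
    ]
    ad_arm = [
        ADArmStudy(
            st.study_id,
            [(r(a[0]), *a[1:]) for a in st.arms],
            binary=st.binary,
            covariate_means=st.covariate_means,
        )
        for st in dataset.ad_arm
    ]
    from .datamodel import IPDStudy

    ipd = [
        IPDStudy(st.study_id, [(y, r(c), x) for y, c, x in st.patients])
        for st in dataset.ipd
    ]
    return NetworkDataset(
        catalog=new_cat,
        ad_contrast=ad_contrast,
        ad_arm=ad_arm,
        ipd=ipd,
        covariate_names=dataset.covariate_names,
        covariate_means=dataset.covariate_means,
    )


# ---------------------------------------------------------------------------
# Likelihood pieces (exposed for tests and reuse)
# ---------------------------------------------------------------------------


def contrast_covariance(study: ADContrastStudy) -> np.ndarray:
    """Sampling covariance S_i of a contrast-level study's y vector.

    Contrasts of a multi-arm study share the reference arm, so they are
    correlated: the common covariance is the reference-arm variance
    ``ref_se^2`` when supplied.  When it is not, the default approximation
    assumes the correlation induced by an equal split of each contrast's
    variance between its two arms, cov_jk = se_j * se_k / 2, which is
    always positive definite.  Two-arm studies are unaffected.
    """
    se = np.array([a[2] for a in study.arms[1:]], dtype=float)
    m = len(se)
    S = np.diag(se**2)
    if m > 1:
        if study.ref_se is not None:
            off = study.ref_se**2
            cov = np.full((m, m), off)
        else:
            cov = 0.5 * np.outer(se, se)
        S = np.where(np.eye(m, dtype=bool), S, cov)
    return S


def loglik_ad(study, params: dict, spec: ADModelSpec) -> float:
    """Log-likelihood contribution of one AD study at given parameters.

    For a contrast study ``params['delta']`` holds the per-contrast means;
    for an arm study ``params['baseline']`` and ``params['delta']`` give the
    reference-arm linear predictor and the non-reference contrasts.
    """
    if isinstance(study, ADContrastStudy):
        if spec.likelihood != "contrast-normal":
            raise DataError("contrast-level study requires the contrast-normal likelihood")
        y = np.array([a[1] for a in study.arms[1:]], dtype=float)
        delta = np.atleast_1d(np.asarray(params["delta"], dtype=float))
        S = contrast_covariance(study)
        resid = y - delta
        sign, logdet = np.linalg.slogdet(S)
        quad = resid @ np.linalg.solve(S, resid)
        return float(-0.5 * (len(y) * math.log(2 * math.pi) + logdet + quad))
    if not isinstance(study, ADArmStudy):
        raise DataError(f"unsupported study type {type(study).__name__}")
    delta = np.concatenate([[0.0], np.atleast_1d(np.asarray(params["delta"], float))])
    mu = float(params["baseline"])
    if spec.likelihood == "arm-binomial-logit":
        if not study.binary:
            raise DataError("binomial likelihood requires binary arm data")
        total = 0.0
        for (arm, dlt) in zip(study.arms, delta):
            _, r, n = arm
            p = expit(mu + dlt)
            total += (
                gammaln(n + 1)
                - gammaln(r + 1)
                - gammaln(n - r + 1)
                + r * math.log(max(p, 1e-300))
                + (n - r) * math.log(max(1 - p, 1e-300))
            )
        return float(total)
    if spec.likelihood == "arm-normal":
        if study.binary:
            raise DataError("normal arm likelihood requires continuous arm data")
        total = 0.0
        for (arm, dlt) in zip(study.arms, delta):
            _, mean, sd, n = arm
            se2 = sd**2 / n
            total += -0.5 * (math.log(2 * math.pi * se2) + (mean - mu - dlt) ** 2 / se2)
        return float(total)
    raise DataError(f"likelihood {spec.likelihood!r} does not apply to arm data")


# ---------------------------------------------------------------------------
# Internal: per-study prepared structures
# ---------------------------------------------------------------------------


class _ContrastData:
    """Stacked contrast-level data with per-study blocks."""

    def __init__(self, studies: list[ADContrastStudy], design: CombinationMatrix):
        self.X: list[np.ndarray] = []
        self.y: list[np.ndarray] = []
        self.S: list[np.ndarray] = []
        self.k: list[int] = []
        row = 0
        for st in studies:
            m = st.n_arms - 1
            self.X.append(design.contrast_rows[row : row + m])
            self.y.append(np.array([a[1] for a in st.arms[1:]], dtype=float))
            self.S.append(contrast_covariance(st))
            self.k.append(st.n_arms)
            row += m
        self.n_rows = row

    def marginal_loglik(self, d: np.ndarray, tau: float) -> float:
        total = 0.0
        for X, y, S, k in zip(self.X, self.y, self.S, self.k):
            V = S + multiarm_re_covariance(tau**2, k)
            resid = y - X @ d
            sign, logdet = np.linalg.slogdet(V)
            total += -0.5 * (len(y) * math.log(2 * math.pi) + logdet
                             + resid @ np.linalg.solve(V, resid))
        return total

    def gls_moments(self, tau: float) -> tuple[np.ndarray, np.ndarray]:
        p = self.X[0].shape[1]
        A = np.zeros((p, p))
        b = np.zeros(p)
        for X, y, S, k in zip(self.X, self.y, self.S, self.k):
            V = S + multiarm_re_covariance(tau**2, k)
            W = np.linalg.inv(V)
            A += X.T @ W @ X
            b += X.T @ W @ y
        return A, b


class _ArmData:
    """Arm-level data grouped for vectorized MH sweeps."""

    def __init__(self, studies: list[ADArmStudy], design: CombinationMatrix, binary: bool):
        self.binary = binary
        self.X: list[np.ndarray] = []
        self.k: list[int] = []
        self.stats: list[tuple] = []
        row = 0
        for st in studies:
            m = st.n_arms - 1
            self.X.append(design.contrast_rows[row : row + m])
            self.k.append(st.n_arms)
            if binary:
                r = np.array([a[1] for a in st.arms], dtype=float)
                n = np.array([a[2] for a in st.arms], dtype=float)
                self.stats.append((r, n))
            else:
                mean = np.array([a[1] for a in st.arms], dtype=float)
                se2 = np.array([a[2] ** 2 / a[3] for a in st.arms], dtype=float)
                self.stats.append((mean, se2))
            row += m
        self.n_studies = len(studies)

    def arm_loglik(self, i: int, mu: float, delta: np.ndarray) -> float:
        eta = mu + np.concatenate([[0.0], delta])
        if self.binary:
            r, n = self.stats[i]
            p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
            return float(np.sum(r * np.log(p) + (n - r) * np.log1p(-p)))
        mean, se2 = self.stats[i]
        return float(np.sum(-0.5 * ((mean - eta) ** 2 / se2 + np.log(2 * math.pi * se2))))


def _prior_precision(
    spec: ADModelSpec, n_main: int, n_pairs: int, pair_var: np.ndarray | None
) -> np.ndarray:
    prec = np.full(n_main + n_pairs, 1.0 / spec.priors.d_sd**2)
    if n_pairs:
        if pair_var is None:  # "full" mode: fixed vague prior on pairs
            prec[n_main:] = 1.0 / spec.priors.d_pair_sd**2
        else:
            prec[n_main:] = 1.0 / pair_var
    return prec


def _mvn_prior_conditional(
    delta: np.ndarray, mean: np.ndarray, tau2: float, j: int
) -> tuple[float, float]:
    """Mean/variance of delta_j | delta_{-j} under MVN(mean, tau2 * P)."""
    m = len(delta)
    if m == 1:
        return float(mean[0]), tau2
    # P = 0.5 I + 0.5 J; Q = P^{-1} = 2 I - (2/(m+1)) J
    qjj = 2.0 - 2.0 / (m + 1)
    cond_var = tau2 / qjj
    off = -2.0 / (m + 1)
    resid = np.delete(delta - mean, j)
    cond_mean = float(mean[j] - (off / qjj) * resid.sum())
    return cond_mean, cond_var


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


def _run_chain(
    rng: np.random.Generator,
    data,
    design: CombinationMatrix,
    spec: ADModelSpec,
    n_iter: int,
    burnin: int,
):
    p_main = design.n_main
    pairs = design.interactions.pairs
    n_pairs = len(pairs)
    p = p_main + n_pairs
    pri = spec.priors
    mode = spec.interaction_mode
    contrast_level = isinstance(data, _ContrastData)

    d = np.zeros(p)
    tau = float(np.exp(pri.tau_ln_mean / 2)) if pri.tau_prior == "lognormal" else 0.2
    incl = np.ones(n_pairs, dtype=int)
    eta = pri.ssvs.eta
    prior_p = np.array([design.interactions.inclusion_prob(pr) for pr in pairs])
    lam = (
        spec.fixed_lambda
        if spec.fixed_lambda is not None
        else (pri.lasso.fixed_lambda or 1.0)
    )
    lam_random = spec.fixed_lambda is None and pri.lasso.fixed_lambda is None
    omega = np.ones(n_pairs)

    tau_scale = AdaptiveScale(1, init=0.5)
    eta_scale = AdaptiveScale(1, init=0.3)
    lam_scale = AdaptiveScale(1, init=0.5)

    if not contrast_level:
        mu = np.zeros(data.n_studies)
        delta = [np.zeros(k - 1) for k in data.k]
        if data.binary:
            for i, (r, n) in enumerate(data.stats):
                phat = np.clip((r + 0.5) / (n + 1.0), 1e-6, 1 - 1e-6)
                mu[i] = math.log(phat[0] / (1 - phat[0]))
                delta[i] = np.log(phat[1:] / (1 - phat[1:])) - mu[i]
        else:
            for i, (mean, se2) in enumerate(data.stats):
                mu[i] = mean[0]
                delta[i] = mean[1:] - mean[0]
        mu_scale = AdaptiveScale(data.n_studies, init=0.3)
        del_scales = [AdaptiveScale(k - 1, init=0.3) for k in data.k]

    kept = {name: [] for name in ("d", "d_pairs", "I_pairs", "tau", "eta", "lambda", "mu")}

    total = burnin + n_iter
    for it in range(total):
        adapting = it < burnin

        # --- pair prior variances for the conjugate d update
        if mode == "ssvs":
            pair_var = np.where(incl == 1, (pri.ssvs.g * eta) ** 2, eta**2)
        elif mode == "lasso":
            pair_var = omega
        else:
            pair_var = None
        prior_prec = _prior_precision(spec, p_main, n_pairs, pair_var)

        # --- d update (conjugate GLS)
        if contrast_level:
            A, b = data.gls_moments(tau)
        else:
            p_ = p
            A = np.zeros((p_, p_))
            b = np.zeros(p_)
            tau2 = tau**2
            for X, dl, k in zip(data.X, delta, data.k):
                W = np.linalg.inv(multiarm_re_covariance(tau2, k))
                A += X.T @ W @ X
                b += X.T @ W @ dl
        A[np.diag_indices_from(A)] += prior_prec
        d = sample_mvn_from_precision(rng, A, b)

        # --- arm-level latent updates
        if not contrast_level:
            tau2 = tau**2
            for i in range(data.n_studies):
                # baseline MH
                s = mu_scale.scales[i]
                prop = mu[i] + s * rng.standard_normal()
                cur_ll = data.arm_loglik(i, mu[i], delta[i])
                new_ll = data.arm_loglik(i, prop, delta[i])
                logr = (new_ll - cur_ll) - (prop**2 - mu[i] ** 2) / (
                    2 * pri.baseline_sd**2
                )
                acc = math.log(rng.uniform()) < logr
                if acc:
                    mu[i] = prop
                if adapting:
                    mu_scale.update(
                        np.eye(data.n_studies)[i] * acc
                        + (1 - np.eye(data.n_studies)[i]) * mu_scale.target
                    )
                # random-effect contrasts, componentwise MH
                mean_i = data.X[i] @ d
                if data.binary:
                    for j in range(len(delta[i])):
                        cm, cv = _mvn_prior_conditional(delta[i], mean_i, tau2, j)
                        sj = del_scales[i].scales[j]
                        propd = delta[i].copy()
                        propd[j] += sj * rng.standard_normal()
                        cur = data.arm_loglik(i, mu[i], delta[i]) - 0.5 * (
                            delta[i][j] - cm
                        ) ** 2 / cv
                        new = data.arm_loglik(i, mu[i], propd) - 0.5 * (
                            propd[j] - cm
                        ) ** 2 / cv
                        accj = math.log(rng.uniform()) < new - cur
                        if accj:
                            delta[i] = propd
                        if adapting:
                            upd = np.full(len(delta[i]), del_scales[i].target)
                            upd[j] = accj
                            del_scales[i].update(upd)
                else:
                    # conjugate: normal likelihood in delta_j
                    mean_arm, se2 = data.stats[i]
                    for j in range(len(delta[i])):
                        cm, cv = _mvn_prior_conditional(delta[i], mean_i, tau2, j)
                        prec = 1.0 / cv + 1.0 / se2[j + 1]
                        m_post = (cm / cv + (mean_arm[j + 1] - mu[i]) / se2[j + 1]) / prec
                        delta[i][j] = m_post + rng.standard_normal() / math.sqrt(prec)
                # conjugate baseline for continuous arms
                if not data.binary:
                    mean_arm, se2 = data.stats[i]
                    resid = mean_arm - np.concatenate([[0.0], delta[i]])
                    prec = (1.0 / se2).sum() + 1.0 / pri.baseline_sd**2
                    m_post = (resid / se2).sum() / prec
                    mu[i] = m_post + rng.standard_normal() / math.sqrt(prec)

        # --- tau MH on log scale
        s = tau_scale.scales[0]
        lt_prop = math.log(tau) + s * rng.standard_normal()
        tau_prop = math.exp(lt_prop)

        def tau_logpost(t: float) -> float:
            lp = pri.log_tau_prior(t) + math.log(t)  # Jacobian of log transform
            if contrast_level:
                return lp + data.marginal_loglik(d, t)
            t2 = t**2
            for X, dl, k in zip(data.X, delta, data.k):
                V = multiarm_re_covariance(t2, k)
                resid = dl - X @ d
                sign, logdet = np.linalg.slogdet(V)
                lp += -0.5 * (logdet + resid @ np.linalg.solve(V, resid))
            return lp

        acc = math.log(rng.uniform()) < tau_logpost(tau_prop) - tau_logpost(tau)
        if acc:
            tau = tau_prop
        if adapting:
            tau_scale.update(np.array([acc]))

        # --- shrinkage blocks
        if mode == "ssvs" and n_pairs:
            dp = d[p_main:]
            probs = indicator_full_conditional(dp, eta, pri.ssvs.g, prior_p)
            incl = (rng.uniform(size=n_pairs) < probs).astype(int)
            if pri.ssvs.eta_random:
                s = eta_scale.scales[0]
                le_prop = math.log(eta) + s * rng.standard_normal()
                eta_prop = math.exp(le_prop)

                def eta_logpost(e: float) -> float:
                    sd = np.where(incl == 1, pri.ssvs.g * e, e)
                    ll = float(np.sum(-np.log(sd) - 0.5 * (dp / sd) ** 2))
                    # half-normal prior on eta, log-scale Jacobian
                    return ll - 0.5 * (e / pri.ssvs.eta_prior_sd) ** 2 + math.log(e)

                acc = math.log(rng.uniform()) < eta_logpost(eta_prop) - eta_logpost(eta)
                if acc:
                    eta = eta_prop
                if adapting:
                    eta_scale.update(np.array([acc]))
        elif mode == "lasso" and n_pairs:
            dp = d[p_main:]
            inv_omega = sample_inverse_gaussian(
                rng, lam / np.maximum(np.abs(dp), 1e-8), lam**2
            )
            omega = 1.0 / inv_omega
            if lam_random:
                s = lam_scale.scales[0]
                ll_prop = math.log(lam) + s * rng.standard_normal()
                lam_prop = math.exp(ll_prop)

                def lam_logpost(l: float) -> float:
                    # omega_j ~ Exp(l^2/2)
                    return (
                        pri.lasso.log_prior(l)
                        + n_pairs * math.log(l**2 / 2)
                        - l**2 * omega.sum() / 2
                        + math.log(l)
                    )

                acc = math.log(rng.uniform()) < lam_logpost(lam_prop) - lam_logpost(lam)
                if acc:
                    lam = lam_prop
                if adapting:
                    lam_scale.update(np.array([acc]))

        if it >= burnin:
            kept["d"].append(d[:p_main].copy())
            if n_pairs:
                kept["d_pairs"].append(d[p_main:].copy())
                if mode == "ssvs":
                    kept["I_pairs"].append(incl.copy())
                    kept["eta"].append(eta)
                if mode == "lasso":
                    kept["lambda"].append(lam)
            kept["tau"].append(tau)
            if not contrast_level:
                kept["mu"].append(mu.copy())

    return {k: np.array(v) for k, v in kept.items() if v}


def fit_ad(
    dataset: NetworkDataset, spec: ADModelSpec, mcmc: MCMCSettings
) -> PosteriorDraws:
    """Fit an aggregate-data (C)NMA model by MCMC.

    Supports contrast-level normal, arm-level binomial-logit, and arm-level
    normal likelihoods; component or treatment level; and no / full / SSVS /
    LASSO interaction handling.  Returns labelled posterior draws with
    split-R-hat diagnostics in ``meta['diagnostics']`` (a warning flag is
    set when any R-hat exceeds 1.01).
    """
    if spec.level == "treatment":
        dataset = treatment_level_dataset(dataset)
        inner = ADModelSpec(
            level="component",
            interaction_mode="none",
            likelihood=spec.likelihood,
            priors=spec.priors,
        )
        draws = fit_ad(dataset, inner, mcmc)
        draws.meta["level"] = "treatment"
        return draws

    interactions = spec.interactions if spec.interaction_mode != "none" else InteractionSet()
    design = build_design(dataset, interactions)

    if spec.likelihood == "contrast-normal":
        if not dataset.ad_contrast or dataset.ad_arm:
            raise DataError("contrast-normal likelihood requires contrast-level studies")
        data = _ContrastData(dataset.ad_contrast, design)
        scale = dataset.ad_contrast[0].scale
        study_ids = [st.study_id for st in dataset.ad_contrast]
    else:
        if not dataset.ad_arm or dataset.ad_contrast:
            raise DataError("arm-level likelihoods require arm-level studies")
        binary = spec.likelihood == "arm-binomial-logit"
        for st in dataset.ad_arm:
            if st.binary != binary:
                raise DataError(
                    f"study {st.study_id}: likelihood {spec.likelihood!r} does not "
                    "match its arm data"
                )
        data = _ArmData(dataset.ad_arm, design, binary)
        scale = "logOR" if binary else "MD"
        study_ids = [st.study_id for st in dataset.ad_arm]

    chains = []
    for rng in mcmc.chain_rngs():
        chains.append(
            _run_chain(rng, data, design, spec, mcmc.iterations, mcmc.burnin)
        )

    params: dict[str, np.ndarray] = {}
    coords: dict[str, list[str]] = {}
    pair_labels = [f"{p}.{q}" for p, q in design.interactions.pairs]
    for name in chains[0]:
        params[name] = np.stack([c[name] for c in chains])
        if name == "d":
            coords[name] = list(design.catalog.codes)
        elif name in ("d_pairs", "I_pairs"):
            coords[name] = pair_labels
        elif name == "mu":
            coords[name] = study_ids

    draws = PosteriorDraws(
        params=params,
        coords=coords,
        meta={
            "model": "ad",
            "level": spec.level,
            "interaction_mode": spec.interaction_mode,
            "likelihood": spec.likelihood,
            "seed": mcmc.seed,
            "chains": mcmc.chains,
            "iterations": mcmc.iterations,
            "burnin": mcmc.burnin,
        },
        design=design,
        scale=scale,
        covariate_names=dataset.covariate_names,
        covariate_means=dataset.covariate_means,
    )
    rhats = {
        name: split_rhat(arr)
        for name, arr in draws.scalar_series().items()
        if name.startswith(("d", "tau"))
    }
    draws.meta["max_rhat"] = max(rhats.values()) if rhats else float("nan")
    draws.meta["rhat_warning"] = bool(draws.meta["max_rhat"] > 1.01)
    if design.zero_pairs:
        draws.meta["zero_pair_warning"] = [list(p) for p in design.zero_pairs]
    return draws


def ssvs_inclusion_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-pair posterior inclusion frequency and mean coefficient.

    The inclusion frequency is the posterior mean of the indicator I_{p.q}:
    the share of MCMC iterations in which the interaction entered the
    model.  Plotting coefficient vs frequency reproduces the V-shaped
    selection scatter."""
    if "I_pairs" not in draws.params:
        raise DataError("inclusion summary requires draws from an SSVS fit")
    freq = draws.stacked("I_pairs").mean(axis=0)
    coef = draws.stacked("d_pairs").mean(axis=0)
    return pd.DataFrame(
        {
            "pair": draws.coords["d_pairs"],
            "inclusion_frequency": freq,
            "posterior_mean": coef,
        }
    )
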