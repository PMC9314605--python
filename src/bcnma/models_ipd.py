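"""One-stage joint models for aggregate plus individual-patient data.

For an IPD study i, patient k randomized to combination t with centered
covariates x, the continuous-outcome model is

    y_ik ~ N(m_ik, sigma_i^2)
    m_ik = alpha_i + beta' x_ik
           + (sum_{q in t} gamma_q - sum_{q in ref} gamma_q)' x_ik
           + delta_i[arm]                    (0 on the study's reference arm)

with study intercepts alpha_i, common prognostic coefficients beta, and
per-component effect-modification vectors gamma_q.  The arm contrasts
delta_i share the same second level as the aggregate studies,
delta_i ~ MVN(X_i d, tau^2 P): conditional (IPD) and marginal (AD)
estimates are pooled as exchangeable.  Aggregate contrast studies may be
adjusted by study-mean covariates, y_i ~ N(delta_i + beta' xbar_i, s_i^2).

Effect-modification coefficients can be shrunk by spike-and-slab selection
or by a conditional Laplace prior (which requires a common sigma across
IPD studies); component-pair interaction terms in d take the same
none / SSVS / LASSO handling as the aggregate-only models.  A binary
outcome replaces the normal likelihood by Bernoulli with a logit link.

Because the reference arm of an IPD study is a convention (results are
invariant to it), it is fixed to the arm whose combination comes first in
canonical order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .datamodel import DataError, IPDStudy, NetworkDataset
from .design import CombinationMatrix, InteractionSet, build_design, contrast_design_row
from .mcmc import (
    AdaptiveScale,
    MCMCSettings,
    PosteriorDraws,
    sample_inverse_gaussian,
    sample_mvn_from_precision,
    split_rhat,
)
from .models_ad import (
    contrast_covariance,
    multiarm_re_covariance,
    treatment_level_dataset,
    _mvn_prior_conditional,
)
from .priors import PriorConfig, conditional_laplace_logdensity, indicator_full_conditional

__all__ = [
    "IPDModelSpec",
    "loglik_ipd_patient",
    "ad_metaregression_mean",
    "fit_joint",
    "mix_imputation_draws",
]


@dataclass(frozen=True)
class IPDModelSpec:
    """Configuration of the joint AD+IPD model."""

    component_level: bool = True
    interaction_mode: str = "none"  # none | ssvs | lasso, on component pairs
    gamma_shrinkage: str = "none"  # none | ssvs | conditional-laplace
    sigma_mode: str = "per-study"  # per-study | common
    ad_metaregression: bool = False
    outcome: str = "continuous"  # continuous | binary
    priors: PriorConfig = field(default_factory=PriorConfig)
    interactions: InteractionSet = field(default_factory=InteractionSet)

    def __post_init__(self):
        if self.interaction_mode not in ("none", "ssvs", "lasso"):
            raise DataError(f"unknown interaction mode {self.interaction_mode!r}")
        if self.gamma_shrinkage not in ("none", "ssvs", "conditional-laplace"):
            raise DataError(f"unknown gamma shrinkage {self.gamma_shrinkage!r}")
        if self.sigma_mode not in ("per-study", "common"):
            raise DataError(f"unknown sigma mode {self.sigma_mode!r}")
        if self.outcome not in ("continuous", "binary"):
            raise DataError(f"unknown outcome type {self.outcome!r}")
        if self.gamma_shrinkage == "conditional-laplace" and self.sigma_mode != "common":
            raise DataError(
                "conditional Laplace shrinkage on gamma requires a common sigma"
            )
        if self.interaction_mode != "none" and not self.component_level:
            raise DataError("component interactions require component-level analysis")


def ad_metaregression_mean(delta_i, beta, xbar_i=None, enabled: bool = True):
    """Adjusted mean of an AD study's relative effect: delta_i + beta' xbar_i.

    With the meta-regression flag off the mean is delta_i regardless of
    xbar_i; with it on, missing study-mean covariates are an error.
    """
    delta_i = np.asarray(delta_i, dtype=float)
    if not enabled:
        return delta_i
    if xbar_i is None:
        raise DataError("AD meta-regression requires study-mean covariates")
    shift = float(np.dot(np.asarray(beta, float), np.asarray(xbar_i, float)))
    return delta_i + shift


def loglik_ipd_patient(
    patient: tuple,
    study_params: dict,
    global_params: dict,
    spec: IPDModelSpec,
    ref_combo,
    catalog,
) -> float:
    """Log-likelihood contribution of one patient record.

    ``patient`` is (y, combination, x); ``study_params`` holds ``alpha``,
    ``delta`` (mapping canonical arm label -> contrast, 0 for the reference)
    and ``sigma``; ``global_params`` holds ``beta`` and ``gamma`` (matrix
    n_components x n_covariates).
    """
    y, combo, x = patient
    x = np.atleast_1d(np.asarray(x, dtype=float))
    beta = np.asarray(global_params["beta"], dtype=float)
    gamma = np.asarray(global_params["gamma"], dtype=float)
    if len(x) != len(beta) or (gamma.size and gamma.shape[1] != len(x)):
        raise DataError("covariate length mismatch")
    z = combo.indicator(catalog) - ref_combo.indicator(catalog)
    em = float(z @ gamma @ x) if gamma.size else 0.0
    label = combo.canonical(catalog)
    delta = study_params["delta"].get(label, 0.0)
    m = study_params["alpha"] + float(beta @ x) + em + delta
    if spec.outcome == "binary":
        p = np.clip(expit(m), 1e-12, 1 - 1e-12)
        return float(y * math.log(p) + (1 - y) * math.log1p(-p))
    sigma = study_params["sigma"]
    return float(-0.5 * (math.log(2 * math.pi * sigma**2) + ((y - m) / sigma) ** 2))


# ---------------------------------------------------------------------------
# Prepared per-study structures
# ---------------------------------------------------------------------------


class _IPDBlock:
    """One IPD study, arranged for vectorized conditional updates."""

    def __init__(self, st: IPDStudy, design: CombinationMatrix, n_cov: int):
        cat = design.catalog
        combos = sorted(st.combinations, key=lambda c: c.canonical(cat))
        self.ref = combos[0]
        self.arms = combos[1:]  # non-reference, canonical order
        self.X = np.array(
            [
                contrast_design_row(self.ref, c, cat, design.interactions)
                for c in self.arms
            ]
        )
        label_to_arm = {c.canonical(cat): j for j, c in enumerate(self.arms)}
        self.y = np.array([p[0] for p in st.patients], dtype=float)
        self.x = (
            np.array([np.atleast_1d(p[2]) for p in st.patients], dtype=float)
            if n_cov
            else np.zeros((len(st.patients), 0))
        )
        # arm index per patient: -1 = reference
        self.arm_idx = np.array(
            [label_to_arm.get(p[1].canonical(cat), -1) for p in st.patients]
        )
        # effect-modification design: em_row = kron(z_main, x)
        zmain = {
            j: (c.indicator(cat) - self.ref.indicator(cat)) for j, c in enumerate(self.arms)
        }
        zmain[-1] = np.zeros(len(cat))
        self.em = np.array(
            [np.kron(zmain[a], xi) for a, xi in zip(self.arm_idx, self.x)]
        )
        self.n = len(self.y)
        self.k = len(combos)
        self.study_id = st.study_id


def _prepare_ad(dataset: NetworkDataset, design: CombinationMatrix):
    """Split design rows among contrast, arm and IPD studies, in that order."""
    blocks = {"contrast": [], "arm": [], "ipd_rows": None}
    row = 0
    for st in dataset.ad_contrast:
        m = st.n_arms - 1
        blocks["contrast"].append(
            {
                "X": design.contrast_rows[row : row + m],
                "y": np.array([a[1] for a in st.arms[1:]], dtype=float),
                "S": contrast_covariance(st),
                "k": st.n_arms,
                "xbar": st.covariate_means,
                "id": st.study_id,
            }
        )
        row += m
    for st in dataset.ad_arm:
        m = st.n_arms - 1
        d = {
            "X": design.contrast_rows[row : row + m],
            "k": st.n_arms,
            "binary": st.binary,
            "id": st.study_id,
            "xbar": st.covariate_means,
        }
        if st.binary:
            d["r"] = np.array([a[1] for a in st.arms], dtype=float)
            d["n"] = np.array([a[2] for a in st.arms], dtype=float)
        else:
            d["mean"] = np.array([a[1] for a in st.arms], dtype=float)
            d["se2"] = np.array([a[2] ** 2 / a[3] for a in st.arms], dtype=float)
        blocks["arm"].append(d)
        row += m
    blocks["ipd_row_start"] = row
    return blocks


def _run_joint_chain(
    rng: np.random.Generator,
    dataset: NetworkDataset,
    design: CombinationMatrix,
    ipd_blocks: list[_IPDBlock],
    ad: dict,
    spec: IPDModelSpec,
    n_iter: int,
    burnin: int,
):
    pri = spec.priors
    cat = design.catalog
    p_main = design.n_main
    pairs = design.interactions.pairs
    n_pairs = len(pairs)
    p = p_main + n_pairs
    n_cov = len(dataset.covariate_names)
    n_ipd = len(ipd_blocks)
    binary = spec.outcome == "binary"

    # --- state
    d = np.zeros(p)
    tau = float(np.exp(pri.tau_ln_mean / 2)) if pri.tau_prior == "lognormal" else 0.2
    alpha = np.array([blk.y.mean() if not binary else 0.0 for blk in ipd_blocks])
    beta = np.zeros(n_cov)
    gamma = np.zeros((p_main, n_cov))
    sigma = np.array([max(blk.y.std(), 0.1) if not binary else 1.0 for blk in ipd_blocks])
    if spec.sigma_mode == "common" and n_ipd:
        sigma[:] = sigma.mean()
    delta_ipd = [np.zeros(blk.k - 1) for blk in ipd_blocks]
    delta_ad = [blk["y"].copy() for blk in ad["contrast"]]
    mu_arm = np.zeros(len(ad["arm"]))
    delta_arm = [np.zeros(b["k"] - 1) for b in ad["arm"]]
    for i, b in enumerate(ad["arm"]):
        if b["binary"]:
            phat = np.clip((b["r"] + 0.5) / (b["n"] + 1.0), 1e-6, 1 - 1e-6)
            mu_arm[i] = math.log(phat[0] / (1 - phat[0]))
            delta_arm[i] = np.log(phat[1:] / (1 - phat[1:])) - mu_arm[i]
        else:
            mu_arm[i] = b["mean"][0]
            delta_arm[i] = b["mean"][1:] - b["mean"][0]

    incl = np.ones(n_pairs, dtype=int)
    eta = pri.ssvs.eta
    prior_p = np.array([design.interactions.inclusion_prob(pr) for pr in pairs])
    lam = pri.lasso.fixed_lambda or 1.0
    lam_random = pri.lasso.fixed_lambda is None
    omega = np.ones(n_pairs)
    # gamma shrinkage state
    g_incl = np.ones(gamma.size, dtype=int)
    g_lam = 1.0
    g_eta = pri.ssvs.eta

    tau_scale = AdaptiveScale(1, init=0.5)
    sig_scale = AdaptiveScale(max(n_ipd, 1), init=0.2)
    eta_scale = AdaptiveScale(1, init=0.3)
    lam_scale = AdaptiveScale(1, init=0.5)
    glam_scale = AdaptiveScale(1, init=0.5)
    gam_scale = AdaptiveScale(max(gamma.size, 1), init=0.2)
    if binary:
        alpha_scale = AdaptiveScale(max(n_ipd, 1), init=0.2)
        beta_scale = AdaptiveScale(max(n_cov, 1), init=0.2)
        deltai_scales = [AdaptiveScale(blk.k - 1, init=0.3) for blk in ipd_blocks]
        mu_scale = AdaptiveScale(max(len(ad["arm"]), 1), init=0.3)
        darm_scales = [AdaptiveScale(b["k"] - 1, init=0.3) for b in ad["arm"]]

    def ipd_linpred(i: int) -> np.ndarray:
        blk = ipd_blocks[i]
        dl = np.concatenate([[0.0], delta_ipd[i]])
        out = alpha[i] + blk.x @ beta + blk.em @ gamma.reshape(-1)
        return out + dl[blk.arm_idx + 1]

    def ipd_loglik(i: int) -> float:
        m = ipd_linpred(i)
        blk = ipd_blocks[i]
        if binary:
            pr = np.clip(expit(m), 1e-12, 1 - 1e-12)
            return float(np.sum(blk.y * np.log(pr) + (1 - blk.y) * np.log1p(-pr)))
        return float(
            -0.5 * np.sum(((blk.y - m) / sigma[i]) ** 2)
            - blk.n * math.log(sigma[i])
        )

    def arm_loglik(i: int) -> float:
        b = ad["arm"][i]
        eta_lin = mu_arm[i] + np.concatenate([[0.0], delta_arm[i]])
        if b["binary"]:
            pr = np.clip(expit(eta_lin), 1e-12, 1 - 1e-12)
            return float(np.sum(b["r"] * np.log(pr) + (b["n"] - b["r"]) * np.log1p(-pr)))
        return float(np.sum(-0.5 * (b["mean"] - eta_lin) ** 2 / b["se2"]))

    kept: dict[str, list] = {
        k: []
        for k in (
            "d", "d_pairs", "I_pairs", "tau", "eta", "lambda", "alpha", "beta",
            "gamma", "I_gamma", "lambda_gamma", "sigma",
        )
    }

    total = burnin + n_iter
    for it in range(total):
        adapting = it < burnin
        tau2 = tau**2

        # ---- pair prior variances and conjugate d update over all deltas
        if spec.interaction_mode == "ssvs" and n_pairs:
            pair_var = np.where(incl == 1, (pri.ssvs.g * eta) ** 2, eta**2)
        elif spec.interaction_mode == "lasso" and n_pairs:
            pair_var = omega
        else:
            pair_var = np.full(n_pairs, pri.d_pair_sd**2)
        prior_prec = np.concatenate(
            [np.full(p_main, 1.0 / pri.d_sd**2), 1.0 / pair_var]
        )
        A = np.diag(prior_prec.copy())
        b_vec = np.zeros(p)
        for blk_list, deltas in (
            (ad["contrast"], delta_ad),
            (ad["arm"], delta_arm),
        ):
            for blkd, dl in zip(blk_list, deltas):
                W = np.linalg.inv(multiarm_re_covariance(tau2, blkd["k"]))
                A += blkd["X"].T @ W @ blkd["X"]
                b_vec += blkd["X"].T @ W @ dl
        for blk, dl in zip(ipd_blocks, delta_ipd):
            W = np.linalg.inv(multiarm_re_covariance(tau2, blk.k))
            A += blk.X.T @ W @ blk.X
            b_vec += blk.X.T @ W @ dl
        d = sample_mvn_from_precision(rng, A, b_vec)

        # ---- AD contrast-level latent deltas (conjugate MVN)
        for blkd, dl in zip(ad["contrast"], delta_ad):
            W_lik = np.linalg.inv(blkd["S"])
            W_pri = np.linalg.inv(multiarm_re_covariance(tau2, blkd["k"]))
            shift = 0.0
            if spec.ad_metaregression:
                shift = float(
                    np.dot(beta, blkd["xbar"]) if blkd["xbar"] is not None else 0.0
                )
                if blkd["xbar"] is None:
                    raise DataError(
                        f"study {blkd['id']}: AD meta-regression needs covariate means"
                    )
            prec = W_lik + W_pri
            lin = W_lik @ (blkd["y"] - shift) + W_pri @ (blkd["X"] @ d)
            dl[:] = sample_mvn_from_precision(rng, prec, lin)

        # ---- AD arm-level studies
        for i, b in enumerate(ad["arm"]):
            mean_i = b["X"] @ d
            if b["binary"]:
                s = mu_scale.scales[i]
                prop = mu_arm[i] + s * rng.standard_normal()
                cur = arm_loglik(i) - mu_arm[i] ** 2 / (2 * pri.baseline_sd**2)
                old = mu_arm[i]
                mu_arm[i] = prop
                new = arm_loglik(i) - prop**2 / (2 * pri.baseline_sd**2)
                acc = math.log(rng.uniform()) < new - cur
                if not acc:
                    mu_arm[i] = old
                if adapting:
                    upd = np.full(max(len(ad["arm"]), 1), mu_scale.target)
                    upd[i] = acc
                    mu_scale.update(upd)
                for j in range(len(delta_arm[i])):
                    cm, cv = _mvn_prior_conditional(delta_arm[i], mean_i, tau2, j)
                    sj = darm_scales[i].scales[j]
                    old_v = delta_arm[i][j]
                    cur = arm_loglik(i) - 0.5 * (old_v - cm) ** 2 / cv
                    delta_arm[i][j] = old_v + sj * rng.standard_normal()
                    new = arm_loglik(i) - 0.5 * (delta_arm[i][j] - cm) ** 2 / cv
                    accj = math.log(rng.uniform()) < new - cur
                    if not accj:
                        delta_arm[i][j] = old_v
                    if adapting:
                        upd = np.full(len(delta_arm[i]), darm_scales[i].target)
                        upd[j] = accj
                        darm_scales[i].update(upd)
            else:
                se2 = b["se2"]
                for j in range(len(delta_arm[i])):
                    cm, cv = _mvn_prior_conditional(delta_arm[i], mean_i, tau2, j)
                    prec = 1.0 / cv + 1.0 / se2[j + 1]
                    m_post = (cm / cv + (b["mean"][j + 1] - mu_arm[i]) / se2[j + 1]) / prec
                    delta_arm[i][j] = m_post + rng.standard_normal() / math.sqrt(prec)
                resid = b["mean"] - np.concatenate([[0.0], delta_arm[i]])
                prec = (1.0 / se2).sum() + 1.0 / pri.baseline_sd**2
                m_post = (resid / se2).sum() / prec
                mu_arm[i] = m_post + rng.standard_normal() / math.sqrt(prec)

        # ---- IPD updates
        for i, blk in enumerate(ipd_blocks):
            mean_i = blk.X @ d
            if binary:
                # alpha MH
                s = alpha_scale.scales[i]
                old = alpha[i]
                cur = ipd_loglik(i) - old**2 / (2 * pri.baseline_sd**2)
                alpha[i] = old + s * rng.standard_normal()
                new = ipd_loglik(i) - alpha[i] ** 2 / (2 * pri.baseline_sd**2)
                acc = math.log(rng.uniform()) < new - cur
                if not acc:
                    alpha[i] = old
                if adapting:
                    upd = np.full(max(n_ipd, 1), alpha_scale.target)
                    upd[i] = acc
                    alpha_scale.update(upd)
                # delta MH
                for j in range(blk.k - 1):
                    cm, cv = _mvn_prior_conditional(delta_ipd[i], mean_i, tau2, j)
                    sj = deltai_scales[i].scales[j]
                    old_v = delta_ipd[i][j]
                    cur = ipd_loglik(i) - 0.5 * (old_v - cm) ** 2 / cv
                    delta_ipd[i][j] = old_v + sj * rng.standard_normal()
                    new = ipd_loglik(i) - 0.5 * (delta_ipd[i][j] - cm) ** 2 / cv
                    accj = math.log(rng.uniform()) < new - cur
                    if not accj:
                        delta_ipd[i][j] = old_v
                    if adapting:
                        upd = np.full(blk.k - 1, deltai_scales[i].target)
                        upd[j] = accj
                        deltai_scales[i].update(upd)
            else:
                s2 = sigma[i] ** 2
                # alpha conjugate
                resid = (
                    blk.y
                    - blk.x @ beta
                    - blk.em @ gamma.reshape(-1)
                    - np.concatenate([[0.0], delta_ipd[i]])[blk.arm_idx + 1]
                )
                prec = blk.n / s2 + 1.0 / pri.baseline_sd**2
                m_post = resid.sum() / s2 / prec
                alpha[i] = m_post + rng.standard_normal() / math.sqrt(prec)
                # delta conjugate per non-reference arm
                base = (
                    blk.y - alpha[i] - blk.x @ beta - blk.em @ gamma.reshape(-1)
                )
                for j in range(blk.k - 1):
                    cm, cv = _mvn_prior_conditional(delta_ipd[i], mean_i, tau2, j)
                    in_arm = blk.arm_idx == j
                    n_a = int(in_arm.sum())
                    prec = 1.0 / cv + n_a / s2
                    m_post = (cm / cv + base[in_arm].sum() / s2) / prec
                    delta_ipd[i][j] = m_post + rng.standard_normal() / math.sqrt(prec)

        # ---- beta (shared prognostic coefficients)
        if n_cov:
            if binary:
                for c in range(n_cov):
                    s = beta_scale.scales[c]
                    old = beta[c]
                    cur = sum(ipd_loglik(i) for i in range(n_ipd)) - old**2 / (
                        2 * pri.ipd.beta_sd**2
                    )
                    beta[c] = old + s * rng.standard_normal()
                    new = sum(ipd_loglik(i) for i in range(n_ipd)) - beta[c] ** 2 / (
                        2 * pri.ipd.beta_sd**2
                    )
                    acc = math.log(rng.uniform()) < new - cur
                    if not acc:
                        beta[c] = old
                    if adapting:
                        upd = np.full(max(n_cov, 1), beta_scale.target)
                        upd[c] = acc
                        beta_scale.update(upd)
            else:
                A_b = np.eye(n_cov) / pri.ipd.beta_sd**2
                b_b = np.zeros(n_cov)
                for i, blk in enumerate(ipd_blocks):
                    s2 = sigma[i] ** 2
                    resid = (
                        blk.y
                        - alpha[i]
                        - blk.em @ gamma.reshape(-1)
                        - np.concatenate([[0.0], delta_ipd[i]])[blk.arm_idx + 1]
                    )
                    A_b += blk.x.T @ blk.x / s2
                    b_b += blk.x.T @ resid / s2
                if spec.ad_metaregression:
                    for blkd, dl in zip(ad["contrast"], delta_ad):
                        if blkd["xbar"] is None:
                            continue
                        xb = np.asarray(blkd["xbar"], float)
                        W = np.linalg.inv(blkd["S"])
                        # y - delta = (beta' xbar) 1 + noise
                        ones = np.ones(len(dl))
                        A_b += np.outer(xb, xb) * float(ones @ W @ ones)
                        b_b += xb * float(ones @ W @ (blkd["y"] - dl))
                beta = sample_mvn_from_precision(rng, A_b, b_b)

        # ---- gamma (effect modification), with optional shrinkage
        if n_cov and gamma.size:
            gvec = gamma.reshape(-1)
            if spec.gamma_shrinkage == "conditional-laplace" and not binary:
                sig_common = sigma[0]
                for c in range(gvec.size):
                    s = gam_scale.scales[c]
                    old = gvec[c]
                    cur = sum(ipd_loglik(i) for i in range(n_ipd)) + (
                        conditional_laplace_logdensity(
                            gvec, g_lam, sig_common, pri.ipd.laplace_convention
                        )
                    )
                    gvec[c] = old + s * rng.standard_normal()
                    gamma[:] = gvec.reshape(gamma.shape)
                    new = sum(ipd_loglik(i) for i in range(n_ipd)) + (
                        conditional_laplace_logdensity(
                            gvec, g_lam, sig_common, pri.ipd.laplace_convention
                        )
                    )
                    acc = math.log(rng.uniform()) < new - cur
                    if not acc:
                        gvec[c] = old
                        gamma[:] = gvec.reshape(gamma.shape)
                    if adapting:
                        upd = np.full(gvec.size, gam_scale.target)
                        upd[c] = acc
                        gam_scale.update(upd)
                # lambda_gamma MH under 1/lambda ~ U(0,5)
                s = glam_scale.scales[0]
                prop = math.exp(math.log(g_lam) + s * rng.standard_normal())

                def glam_logpost(l: float) -> float:
                    return (
                        pri.lasso.log_prior(l)
                        + conditional_laplace_logdensity(
                            gvec, l, sigma[0], pri.ipd.laplace_convention
                        )
                        + math.log(l)
                    )

                acc = math.log(rng.uniform()) < glam_logpost(prop) - glam_logpost(g_lam)
                if acc:
                    g_lam = prop
                if adapting:
                    glam_scale.update(np.array([acc]))
            elif binary:
                for c in range(gvec.size):
                    prior_var = (
                        ((pri.ssvs.g * g_eta) ** 2 if g_incl[c] else g_eta**2)
                        if spec.gamma_shrinkage == "ssvs"
                        else pri.ipd.gamma_sd**2
                    )
                    s = gam_scale.scales[c]
                    old = gvec[c]
                    cur = sum(ipd_loglik(i) for i in range(n_ipd)) - old**2 / (
                        2 * prior_var
                    )
                    gvec[c] = old + s * rng.standard_normal()
                    gamma[:] = gvec.reshape(gamma.shape)
                    new = sum(ipd_loglik(i) for i in range(n_ipd)) - gvec[c] ** 2 / (
                        2 * prior_var
                    )
                    acc = math.log(rng.uniform()) < new - cur
                    if not acc:
                        gvec[c] = old
                        gamma[:] = gvec.reshape(gamma.shape)
                    if adapting:
                        upd = np.full(gvec.size, gam_scale.target)
                        upd[c] = acc
                        gam_scale.update(upd)
            else:
                if spec.gamma_shrinkage == "ssvs":
                    g_var = np.where(
                        g_incl == 1, (pri.ssvs.g * g_eta) ** 2, g_eta**2
                    )
                else:
                    g_var = np.full(gvec.size, pri.ipd.gamma_sd**2)
                A_g = np.diag(1.0 / g_var)
                b_g = np.zeros(gvec.size)
                for i, blk in enumerate(ipd_blocks):
                    s2 = sigma[i] ** 2
                    resid = (
                        blk.y
                        - alpha[i]
                        - blk.x @ beta
                        - np.concatenate([[0.0], delta_ipd[i]])[blk.arm_idx + 1]
                    )
                    A_g += blk.em.T @ blk.em / s2
                    b_g += blk.em.T @ resid / s2
                gvec = sample_mvn_from_precision(rng, A_g, b_g)
                gamma = gvec.reshape(gamma.shape)
            if spec.gamma_shrinkage == "ssvs":
                probs = indicator_full_conditional(gvec, g_eta, pri.ssvs.g, 0.5)
                g_incl = (rng.uniform(size=gvec.size) < probs).astype(int)

        # ---- sigma
        if not binary and n_ipd:
            def sig_loglik(i: int, s: float) -> float:
                m = ipd_linpred(i)
                blk = ipd_blocks[i]
                return float(
                    -blk.n * math.log(s) - 0.5 * np.sum((blk.y - m) ** 2) / s**2
                )

            def sig_logprior(s: float) -> float:
                lp = -0.5 * (s / pri.ipd.sigma_halfnormal_sd) ** 2 + math.log(s)
                if spec.gamma_shrinkage == "conditional-laplace":
                    lp += conditional_laplace_logdensity(
                        gamma.reshape(-1), g_lam, s, pri.ipd.laplace_convention
                    )
                return lp

            if spec.sigma_mode == "common":
                s = sig_scale.scales[0]
                prop = math.exp(math.log(sigma[0]) + s * rng.standard_normal())
                cur = sum(sig_loglik(i, sigma[0]) for i in range(n_ipd)) + sig_logprior(
                    sigma[0]
                )
                new = sum(sig_loglik(i, prop) for i in range(n_ipd)) + sig_logprior(prop)
                acc = math.log(rng.uniform()) < new - cur
                if acc:
                    sigma[:] = prop
                if adapting:
                    upd = np.full(max(n_ipd, 1), sig_scale.target)
                    upd[0] = acc
                    sig_scale.update(upd)
            else:
                for i in range(n_ipd):
                    s = sig_scale.scales[i]
                    prop = math.exp(math.log(sigma[i]) + s * rng.standard_normal())
                    cur = sig_loglik(i, sigma[i]) + sig_logprior(sigma[i])
                    new = sig_loglik(i, prop) + sig_logprior(prop)
                    acc = math.log(rng.uniform()) < new - cur
                    if acc:
                        sigma[i] = prop
                    if adapting:
                        upd = np.full(max(n_ipd, 1), sig_scale.target)
                        upd[i] = acc
                        sig_scale.update(upd)

        # ---- tau MH over all study random effects
        all_blocks = (
            [(b["X"], dl, b["k"]) for b, dl in zip(ad["contrast"], delta_ad)]
            + [(b["X"], dl, b["k"]) for b, dl in zip(ad["arm"], delta_arm)]
            + [(blk.X, dl, blk.k) for blk, dl in zip(ipd_blocks, delta_ipd)]
        )
        s = tau_scale.scales[0]
        prop = math.exp(math.log(tau) + s * rng.standard_normal())

        def tau_logpost(t: float) -> float:
            lp = pri.log_tau_prior(t) + math.log(t)
            t2 = t**2
            for X, dl, k in all_blocks:
                V = multiarm_re_covariance(t2, k)
                resid = dl - X @ d
                sign, logdet = np.linalg.slogdet(V)
                lp += -0.5 * (logdet + resid @ np.linalg.solve(V, resid))
            return lp

        acc = math.log(rng.uniform()) < tau_logpost(prop) - tau_logpost(tau)
        if acc:
            tau = prop
        if adapting:
            tau_scale.update(np.array([acc]))

        # ---- component-pair shrinkage blocks
        if spec.interaction_mode == "ssvs" and n_pairs:
            dp = d[p_main:]
            probs = indicator_full_conditional(dp, eta, pri.ssvs.g, prior_p)
            incl = (rng.uniform(size=n_pairs) < probs).astype(int)
            if pri.ssvs.eta_random:
                s = eta_scale.scales[0]
                prop = math.exp(math.log(eta) + s * rng.standard_normal())

                def eta_logpost(e: float) -> float:
                    sd = np.where(incl == 1, pri.ssvs.g * e, e)
                    return (
                        float(np.sum(-np.log(sd) - 0.5 * (dp / sd) ** 2))
                        - 0.5 * (e / pri.ssvs.eta_prior_sd) ** 2
                        + math.log(e)
                    )

                acc = math.log(rng.uniform()) < eta_logpost(prop) - eta_logpost(eta)
                if acc:
                    eta = prop
                if adapting:
                    eta_scale.update(np.array([acc]))
        elif spec.interaction_mode == "lasso" and n_pairs:
            dp = d[p_main:]
            inv_omega = sample_inverse_gaussian(
                rng, lam / np.maximum(np.abs(dp), 1e-8), lam**2
            )
            omega = 1.0 / inv_omega
            if lam_random:
                s = lam_scale.scales[0]
                prop = math.exp(math.log(lam) + s * rng.standard_normal())

                def lam_logpost(l: float) -> float:
                    return (
                        pri.lasso.log_prior(l)
                        + n_pairs * math.log(l**2 / 2)
                        - l**2 * omega.sum() / 2
                        + math.log(l)
                    )

                acc = math.log(rng.uniform()) < lam_logpost(prop) - lam_logpost(lam)
                if acc:
                    lam = prop
                if adapting:
                    lam_scale.update(np.array([acc]))

        # ---- record
        if it >= burnin:
            kept["d"].append(d[:p_main].copy())
            if n_pairs:
                kept["d_pairs"].append(d[p_main:].copy())
                if spec.interaction_mode == "ssvs":
                    kept["I_pairs"].append(incl.copy())
                    kept["eta"].append(eta)
                if spec.interaction_mode == "lasso":
                    kept["lambda"].append(lam)
            kept["tau"].append(tau)
            if n_ipd:
                kept["alpha"].append(alpha.copy())
                if not binary:
                    kept["sigma"].append(
                        np.array([sigma[0]]) if spec.sigma_mode == "common" else sigma.copy()
                    )
            if n_cov:
                kept["beta"].append(beta.copy())
                if gamma.size:
                    kept["gamma"].append(gamma.reshape(-1).copy())
                    if spec.gamma_shrinkage == "ssvs":
                        kept["I_gamma"].append(g_incl.copy())
                    if spec.gamma_shrinkage == "conditional-laplace":
                        kept["lambda_gamma"].append(g_lam)

    return {k: np.array(v) for k, v in kept.items() if v}


def fit_joint(
    dataset: NetworkDataset, spec: IPDModelSpec, mcmc: MCMCSettings
) -> PosteriorDraws:
    """Fit the one-stage joint AD+IPD (C)NMA model by MCMC.

    Any mix of contrast-level AD, arm-level AD and IPD studies is accepted
    (at least one study required).  With ``component_level=False`` each
    distinct combination is its own treatment (standard IPD-NMA).
    """
    if not spec.component_level:
        dataset = treatment_level_dataset(dataset)
        inner_spec = IPDModelSpec(
            component_level=True,
            gamma_shrinkage=spec.gamma_shrinkage,
            sigma_mode=spec.sigma_mode,
            ad_metaregression=spec.ad_metaregression,
            outcome=spec.outcome,
            priors=spec.priors,
        )
        draws = fit_joint(dataset, inner_spec, mcmc)
        draws.meta["level"] = "treatment"
        return draws

    interactions = (
        spec.interactions if spec.interaction_mode != "none" else InteractionSet()
    )
    design = build_design(dataset, interactions)
    n_cov = len(dataset.covariate_names)
    ad = _prepare_ad(dataset, design)
    ipd_blocks = [_IPDBlock(st, design, n_cov) for st in dataset.ipd]
    if spec.outcome == "binary":
        for st in dataset.ipd:
            ys = {p[0] for p in st.patients}
            if not ys <= {0, 1, 0.0, 1.0}:
                raise DataError(f"study {st.study_id}: binary outcome must be 0/1")

    chains = [
        _run_joint_chain(
            rng, dataset, design, ipd_blocks, ad, spec, mcmc.iterations, mcmc.burnin
        )
        for rng in mcmc.chain_rngs()
    ]

    params: dict[str, np.ndarray] = {}
    coords: dict[str, list[str]] = {}
    pair_labels = [f"{p}.{q}" for p, q in design.interactions.pairs]
    gamma_labels = [
        f"{code}:{cov}"
        for code in design.catalog.codes
        for cov in dataset.covariate_names
    ]
    ipd_ids = [st.study_id for st in dataset.ipd]
    for name in chains[0]:
        params[name] = np.stack([c[name] for c in chains])
        if name == "d":
            coords[name] = list(design.catalog.codes)
        elif name in ("d_pairs", "I_pairs"):
            coords[name] = pair_labels
        elif name in ("gamma", "I_gamma"):
            coords[name] = gamma_labels
        elif name == "alpha":
            coords[name] = ipd_ids
        elif name == "sigma":
            coords[name] = (
                ["common"] if spec.sigma_mode == "common" else ipd_ids
            )
        elif name == "beta":
            coords[name] = list(dataset.covariate_names)

    scale = (
        dataset.ad_contrast[0].scale
        if dataset.ad_contrast
        else ("logOR" if spec.outcome == "binary" else "MD")
    )
    draws = PosteriorDraws(
        params=params,
        coords=coords,
        meta={
            "model": "joint",
            "level": "component" if spec.component_level else "treatment",
            "interaction_mode": spec.interaction_mode,
            "gamma_shrinkage": spec.gamma_shrinkage,
            "sigma_mode": spec.sigma_mode,
            "outcome": spec.outcome,
            "ad_metaregression": spec.ad_metaregression,
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
        if name.startswith(("d", "tau", "beta"))
    }
    draws.meta["max_rhat"] = max(rhats.values()) if rhats else float("nan")
    draws.meta["rhat_warning"] = bool(draws.meta["max_rhat"] > 1.01)
    return draws


def mix_imputation_draws(fits: list[PosteriorDraws]) -> PosteriorDraws:
    """Pool posterior draws across per-imputation fits.

    Fitting the model once per imputed dataset and concatenating the kept
    draws summarizes the posterior under imputation uncertainty.  All fits
    must share parameter blocks and iteration counts; chains are stacked,
    so m fits of c chains x n draws yield m*c*n mixed draws.
    """
    if not fits:
        raise DataError("no fits to mix")
    if len(fits) == 1:
        return fits[0]
    first = fits[0]
    for f in fits[1:]:
        if set(f.params) != set(first.params):
            raise DataError(
                "imputation fits disagree on parameter blocks: "
                f"{sorted(set(f.params) ^ set(first.params))}"
            )
        for name in first.params:
            if f.params[name].shape[1:] != first.params[name].shape[1:]:
                raise DataError(f"imputation fits disagree on shape of {name!r}")
    params = {
        name: np.concatenate([f.params[name] for f in fits], axis=0)
        for name in first.params
    }
    meta = dict(first.meta)
    meta["n_imputations"] = len(fits)
    meta["imputation_seeds"] = [f.meta.get("seed") for f in fits]
    return PosteriorDraws(
        params=params,
        coords=first.coords,
        meta=meta,
        design=first.design,
        scale=first.scale,
        covariate_names=first.covariate_names,
        covariate_means=first.covariate_means,
    )
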