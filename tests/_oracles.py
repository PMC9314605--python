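"""Independent reference implementations used only to check the package.

These deliberately take different computational routes from the library:
the pairwise meta-analysis sampler uses a centered parameterization with
explicit per-study effects (the library marginalizes them), and the rank
oracle uses exact rational arithmetic via sympy (the library uses an SVD).
"""

from __future__ import annotations

import math

import numpy as np


def pairwise_re_ma_gibbs(
    y: np.ndarray,
    se: np.ndarray,
    seed: int,
    mu_prior_var: float,
    tau_ln_mean: float = -1.67,
    tau_ln_sd: float = 1.472,
    n_iter: int = 12000,
    burnin: int = 2000,
) -> dict[str, np.ndarray]:
    """Bayesian random-effects pairwise meta-analysis, centered Gibbs.

    Model: y_i ~ N(theta_i, se_i^2), theta_i ~ N(mu, tau^2),
    mu ~ N(0, mu_prior_var), tau^2 ~ LN(tau_ln_mean, tau_ln_sd^2).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    s2 = np.asarray(se, float) ** 2
    n = len(y)
    mu, tau = 0.0, 0.3
    theta = y.copy()
    keep_mu, keep_tau = [], []
    prop_sd = 0.5
    for it in range(n_iter):
        prec = 1.0 / s2 + 1.0 / tau**2
        m = (y / s2 + mu / tau**2) / prec
        theta = m + rng.standard_normal(n) / np.sqrt(prec)
        prec_mu = n / tau**2 + 1.0 / mu_prior_var
        mu = theta.sum() / tau**2 / prec_mu + rng.standard_normal() / math.sqrt(prec_mu)

        def logpost(t: float) -> float:
            lt2 = 2.0 * math.log(t)
            prior = (
                -0.5 * ((lt2 - tau_ln_mean) / tau_ln_sd) ** 2 - lt2 + math.log(2 * t)
            )
            lik = -n * math.log(t) - 0.5 * np.sum((theta - mu) ** 2) / t**2
            return prior + lik + math.log(t)  # log-scale proposal Jacobian

        prop = math.exp(math.log(tau) + prop_sd * rng.standard_normal())
        if math.log(rng.uniform()) < logpost(prop) - logpost(tau):
            tau = prop
        if it >= burnin:
            keep_mu.append(mu)
            keep_tau.append(tau)
    return {"mu": np.array(keep_mu), "tau": np.array(keep_tau)}


def exact_rank(matrix: np.ndarray) -> int:
    """Matrix rank by exact rational arithmetic (design entries are 0/±1)."""
    import sympy

    return int(sympy.Matrix(matrix.astype(int)).rank())
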