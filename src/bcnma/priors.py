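"""Prior distributions for the CNMA model family.

The defaults follow common practice for binary-outcome networks: vague
normals ``N(0, 10^2)`` on component effects and study baselines, an
empirically informed lognormal on the heterogeneity variance
``tau^2 ~ LN(-1.67, 1.472^2)``, a spike-and-slab mixture for interaction
terms (``eta ~ N(0, 10^-2)`` truncated to eta > 0, slab factor ``g = 100``),
and an inverse-uniform hyperprior on the LASSO rate, ``1/lambda ~ U(0, 5)``.

The spike-and-slab prior for an interaction coefficient d given its
inclusion indicator I is

    d | I  ~  (1 - I) N(0, eta^2) + I N(0, g^2 eta^2)

so I = 0 pins d (practically) to zero while I = 1 frees it.  The Gibbs
update of I given d is the posterior odds of slab vs spike times the prior
inclusion probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "PriorConfig",
    "SSVSPrior",
    "LassoPrior",
    "IPDPriors",
    "spike_slab_logdensity",
    "indicator_full_conditional",
    "laplace_logdensity",
    "conditional_laplace_logdensity",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _norm_logpdf(x, sd):
    x = np.asarray(x, dtype=float)
    return -_LOG_SQRT_2PI - np.log(sd) - 0.5 * (x / sd) ** 2


@dataclass(frozen=True)
class SSVSPrior:
    """Spike-and-slab settings: spike scale eta (fixed or random) and slab
    factor g.  ``eta_random`` uses a half-normal prior with sd ``eta_prior_sd``
    (a scale cannot be negative); ``eta`` is the fixed value otherwise."""

    g: float = 100.0
    eta: float = 0.1
    eta_random: bool = True
    eta_prior_sd: float = 0.1

    def __post_init__(self):
        if self.g <= 1:
            raise ValueError("slab factor g must exceed 1")
        if self.eta <= 0 or self.eta_prior_sd <= 0:
            raise ValueError("eta scales must be positive")


@dataclass(frozen=True)
class LassoPrior:
    """Bayesian LASSO rate lambda: fixed, or random with 1/lambda ~ U(0, b)
    (default b = 5), or half-normal on 1/lambda as a sensitivity option."""

    fixed_lambda: float | None = None
    inv_uniform_upper: float = 5.0
    inv_halfnormal_sd: float | None = None  # alternative: 1/lambda ~ N(0, sd^2)I(0,)

    def __post_init__(self):
        if self.fixed_lambda is not None and self.fixed_lambda <= 0:
            raise ValueError("lambda must be positive")
        if self.inv_uniform_upper <= 0:
            raise ValueError("inverse-uniform upper bound must be positive")

    def log_prior(self, lam: float) -> float:
        """Log prior density of lambda under the active hyperprior."""
        if lam <= 0:
            return -np.inf
        if self.fixed_lambda is not None:
            return 0.0
        if self.inv_halfnormal_sd is not None:
            # 1/lambda half-normal => p(lam) ∝ exp(-1/(2 sd^2 lam^2)) / lam^2
            sd = self.inv_halfnormal_sd
            return -2.0 * math.log(lam) - 0.5 / (sd * lam) ** 2
        # 1/lambda ~ U(0, b)  =>  p(lam) = 1/(b lam^2) for lam > 1/b
        if lam < 1.0 / self.inv_uniform_upper:
            return -np.inf
        return -2.0 * math.log(lam)


@dataclass(frozen=True)
class IPDPriors:
    """Priors specific to the IPD part: prognostic coefficients beta,
    effect-modification coefficients gamma, within-study sd sigma."""

    beta_sd: float = 10.0
    gamma_sd: float = 10.0
    gamma_shrinkage: str = "none"  # none | ssvs | conditional-laplace
    sigma_halfnormal_sd: float = 10.0
    common_sigma: bool = False
    # exponent convention of the conditional Laplace prior, see
    # conditional_laplace_logdensity
    laplace_convention: str = "sigma-squared"

    def __post_init__(self):
        if self.gamma_shrinkage not in ("none", "ssvs", "conditional-laplace"):
            raise ValueError(f"unknown gamma shrinkage {self.gamma_shrinkage!r}")
        if self.laplace_convention not in ("sigma-squared", "park-casella"):
            raise ValueError(f"unknown Laplace convention {self.laplace_convention!r}")
        if self.gamma_shrinkage == "conditional-laplace" and not self.common_sigma:
            raise ValueError(
                "conditional Laplace shrinkage on gamma requires a common sigma "
                "across IPD studies"
            )


@dataclass(frozen=True)
class PriorConfig:
    """Every hyperparameter of the CNMA model family in one place.

    ``tau_prior`` selects the heterogeneity prior: "lognormal" puts
    ``tau^2 ~ LN(tau_ln_mean, tau_ln_sd^2)``; "half-normal" puts
    ``tau ~ N(0, tau_hn_sd^2)I(0,)``; "uniform" puts ``tau ~ U(0, tau_upper)``.
    """

    d_sd: float = 10.0
    baseline_sd: float = 10.0
    tau_prior: str = "lognormal"
    tau_ln_mean: float = -1.67
    tau_ln_sd: float = 1.472
    tau_hn_sd: float = 10.0
    tau_upper: float = 5.0
    ssvs: SSVSPrior = field(default_factory=SSVSPrior)
    lasso: LassoPrior = field(default_factory=LassoPrior)
    ipd: IPDPriors = field(default_factory=IPDPriors)
    # prior sd of interaction terms when included without shrinkage
    d_pair_sd: float = 10.0

    def __post_init__(self):
        if self.tau_prior not in ("lognormal", "half-normal", "uniform"):
            raise ValueError(f"unknown tau prior {self.tau_prior!r}")
        for name in ("d_sd", "baseline_sd", "tau_ln_sd", "tau_hn_sd", "tau_upper", "d_pair_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def log_tau_prior(self, tau: float) -> float:
        """Log prior density of the heterogeneity SD tau."""
        if tau <= 0:
            return -np.inf
        if self.tau_prior == "lognormal":
            # tau^2 ~ LN(m, s^2); change of variables to tau adds log(2 tau)
            lt2 = 2.0 * math.log(tau)
            return (
                float(_norm_logpdf(lt2 - self.tau_ln_mean, self.tau_ln_sd))
                - lt2
                + math.log(2.0 * tau)
            )
        if self.tau_prior == "half-normal":
            return float(_norm_logpdf(tau, self.tau_hn_sd))
        return 0.0 if tau <= self.tau_upper else -np.inf

    def with_(self, **kwargs) -> "PriorConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PriorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ssvs = SSVSPrior(**raw.pop("ssvs", {}))
        lasso = LassoPrior(**raw.pop("lasso", {}))
        ipd = IPDPriors(**raw.pop("ipd", {}))
        return cls(ssvs=ssvs, lasso=lasso, ipd=ipd, **raw)


# ---------------------------------------------------------------------------
# Densities and conditionals
# ---------------------------------------------------------------------------


def spike_slab_logdensity(d, indicator, eta: float, g: float):
    """Log density of an interaction coefficient under its indicator.

    indicator 0 selects the spike N(0, eta^2); indicator 1 the slab
    N(0, g^2 eta^2).  Vectorized over ``d``/``indicator``.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if g <= 1:
        raise ValueError("g must exceed 1")
    ind = np.asarray(indicator)
    sd = np.where(ind == 1, g * eta, eta)
    return _norm_logpdf(d, sd)


def indicator_full_conditional(d, eta: float, g: float, prior_p):
    """Gibbs update P(I = 1 | d) for a spike-and-slab indicator.

    Equals ``p phi(d; 0, g^2 eta^2) / [p phi(d; 0, g^2 eta^2) +
    (1-p) phi(d; 0, eta^2)]`` with p the prior inclusion probability.
    Computed on the log scale for numerical safety; vectorized.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if g <= 1:
        raise ValueError("g must exceed 1")
    prior_p = np.asarray(prior_p, dtype=float)
    if np.any((prior_p <= 0) | (prior_p >= 1)):
        raise ValueError("prior inclusion probability must be in (0,1)")
    log_slab = _norm_logpdf(d, g * eta) + np.log(prior_p)
    log_spike = _norm_logpdf(d, eta) + np.log1p(-prior_p)
    m = np.maximum(log_slab, log_spike)
    w1 = np.exp(log_slab - m)
    return w1 / (w1 + np.exp(log_spike - m))


def laplace_logdensity(d, lam: float):
    """Log density of the double-exponential prior, log(lam/2) - lam |d|."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return math.log(lam / 2.0) - lam * np.abs(np.asarray(d, dtype=float))


def conditional_laplace_logdensity(
    gamma, lam: float, sigma: float, convention: str = "sigma-squared"
):
    """Log density of the conditional Laplace prior on effect-modification
    coefficients, summed over coordinates.

    Two exponent conventions are supported and must be chosen explicitly:

    * ``"sigma-squared"`` (default): per coordinate
      ``log(lam/(2 sigma)) - lam |gamma_k| / sigma^2``.  This form does not
      integrate to one in general (its integral is ``sigma``).
    * ``"park-casella"``: ``log(lam/(2 sigma)) - lam |gamma_k| / sigma``,
      which is a proper Laplace density with scale ``sigma/lam`` and is the
      convention that normalizes.

    Requires the common-sigma model; the caller enforces that mode.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if convention not in ("sigma-squared", "park-casella"):
        raise ValueError(f"unknown convention {convention!r}")
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    denom = sigma**2 if convention == "sigma-squared" else sigma
    terms = math.log(lam / (2.0 * sigma)) - lam * np.abs(gamma) / denom
    return float(terms.sum())
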