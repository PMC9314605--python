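"""Synthetic component-network data with known generating truth.

Every model in the package is verifiable by parameter recovery: the
generator inverts the model likelihoods, so fitting the generating model
to a simulated dataset must recover the estimable parameters.  A dataset
is produced from a :class:`SyntheticTruth` (generating parameters plus a
design plan) and a seed; the same seed reproduces the dataset exactly.

The default scenario is a moderate-size network of 6 components: 40
two-arm and 5 three-arm studies whose arms are drawn from a fixed pool of
combinations, heterogeneity tau = 0.3, component effects of realistic
magnitude (|d| up to 0.8 on the contrast scale), and a single true
pairwise interaction of 1.0 between the first two components — sized so
that spike-and-slab selection has a real signal to find and a handful of
co-occurring null pairs to reject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    ADArmStudy,
    ADContrastStudy,
    ComponentCatalog,
    DataError,
    IPDStudy,
    NetworkDataset,
    TreatmentCombination,
)
from .design import InteractionSet
from .models_ad import multiarm_re_covariance, ssvs_inclusion_summary
from .mcmc import PosteriorDraws

__all__ = [
    "SimulationPlan",
    "SyntheticTruth",
    "default_plan",
    "simulate_ad",
    "simulate_ipd",
    "selection_operating_characteristics",
]


@dataclass(frozen=True)
class SimulationPlan:
    """Design plan: how many studies, which combinations, noise levels."""

    pool: tuple[str, ...]  # combination labels, "+"-separated
    n_two_arm: int = 40
    n_three_arm: int = 5
    likelihood: str = "contrast"  # contrast | arm-binomial | arm-normal
    se_range: tuple[float, float] = (0.2, 0.4)  # contrast-level SE draw
    arm_size: int = 100  # arm-level sample size per arm
    baseline_mean: float = -0.5  # arm-level baseline (logit or mean)
    baseline_sd: float = 0.5
    arm_sd: float = 1.0  # continuous arm-level outcome SD
    # IPD part
    n_ipd_studies: int = 0
    patients_per_arm: int = 60
    covariates: tuple[str, ...] = ()  # each "normal" or "bernoulli"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.5

    def __post_init__(self):
        if not self.pool:
            raise DataError("combination pool is empty")
        if self.likelihood not in ("contrast", "arm-binomial", "arm-normal"):
            raise DataError(f"unknown plan likelihood {self.likelihood!r}")
        for c in self.covariates:
            if c not in ("normal", "bernoulli"):
                raise DataError(f"unknown covariate kind {c!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters paired with a design plan."""

    catalog: ComponentCatalog
    d: np.ndarray  # per component, catalog order
    tau: float
    d_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    beta: np.ndarray | None = None  # per covariate
    gamma: np.ndarray | None = None  # (n_components, n_covariates)
    sigma: float = 1.0
    plan: SimulationPlan | None = None

    def __post_init__(self):
        if self.tau < 0 or self.sigma < 0:
            raise DataError("tau and sigma must be non-negative")
        if len(self.d) != len(self.catalog):
            raise DataError("d must have one entry per catalog component")
        for p, q in self.d_pairs:
            if p not in self.catalog or q not in self.catalog:
                raise DataError(f"interaction pair ({p},{q}) not in catalog")

    def interaction_set(self) -> InteractionSet:
        return InteractionSet(pairs=tuple(self.d_pairs))

    def full_coefficients(self, interactions: InteractionSet) -> np.ndarray:
        """d stacked with pair coefficients in the order of ``interactions``."""
        pair_vals = [
            self.d_pairs.get(tuple(sorted(p)), 0.0) for p in interactions.pairs
        ]
        return np.concatenate([np.asarray(self.d, float), np.array(pair_vals)])

    def combination_effect(self, combo: TreatmentCombination) -> float:
        """theta_T = sum of member effects plus any member-pair interactions."""
        theta = sum(
            self.d[self.catalog.index(c)] for c in combo.members
        )
        for (p, q), v in self.d_pairs.items():
            if p in combo.members and q in combo.members:
                theta += v
        return float(theta)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "codes": list(self.catalog.codes),
            "d": np.asarray(self.d, float).tolist(),
            "tau": self.tau,
            "d_pairs": {f"{p}+{q}": v for (p, q), v in self.d_pairs.items()},
            "beta": None if self.beta is None else np.asarray(self.beta).tolist(),
            "gamma": None if self.gamma is None else np.asarray(self.gamma).tolist(),
            "sigma": self.sigma,
            "plan": None if self.plan is None else self.plan.__dict__
            | {"pool": list(self.plan.pool), "covariates": list(self.plan.covariates),
               "se_range": list(self.plan.se_range)},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        plan = None
        if raw.get("plan"):
            pr = dict(raw["plan"])
            pr["pool"] = tuple(pr["pool"])
            pr["covariates"] = tuple(pr["covariates"])
            pr["se_range"] = tuple(pr["se_range"])
            plan = SimulationPlan(**pr)
        return cls(
            catalog=ComponentCatalog(tuple(raw["codes"])),
            d=np.array(raw["d"], float),
            tau=float(raw["tau"]),
            d_pairs={
                tuple(k.split("+")): float(v) for k, v in raw.get("d_pairs", {}).items()
            },
            beta=None if raw.get("beta") is None else np.array(raw["beta"], float),
            gamma=None if raw.get("gamma") is None else np.array(raw["gamma"], float),
            sigma=float(raw.get("sigma", 1.0)),
            plan=plan,
        )


def default_plan() -> SyntheticTruth:
    """The package's reference scenario (see module docstring)."""
    catalog = ComponentCatalog(("a", "b", "c", "d", "e", "f"))
    pool = ("a", "b", "c", "d", "e", "f", "a + b", "a + b + c", "c + d", "b + e")
    plan = SimulationPlan(pool=pool, n_two_arm=40, n_three_arm=5)
    return SyntheticTruth(
        catalog=catalog,
        d=np.array([-0.8, 0.5, -0.3, 0.4, 0.0, -0.5]),
        tau=0.3,
        d_pairs={("a", "b"): 1.0},
        plan=plan,
    )


def ipd_plan(
    n_ipd_studies: int = 4,
    n_ad_studies: int = 10,
    covariates: tuple[str, ...] = ("normal", "normal", "bernoulli"),
) -> SyntheticTruth:
    """A joint AD+IPD scenario over 4 components with prognostic and
    effect-modifying covariates (emulating a severity/age/gender mix)."""
    catalog = ComponentCatalog(("a", "b", "c", "d"))
    pool = ("a", "b", "c", "d", "a + b", "c + d", "a + c")
    plan = SimulationPlan(
        pool=pool,
        n_two_arm=n_ad_studies,
        n_three_arm=0,
        n_ipd_studies=n_ipd_studies,
        covariates=covariates,
        patients_per_arm=60,
    )
    rngless_gamma = np.array(
        [
            [0.5, 0.0, 0.0],
            [0.0, -0.3, 0.0],
            [0.0, 0.0, 0.0],
            [-0.4, 0.0, 0.2],
        ]
    )[:, : len(covariates)]
    return SyntheticTruth(
        catalog=catalog,
        d=np.array([-0.6, 0.4, 0.0, -0.3]),
        tau=0.25,
        beta=np.array([0.8, -0.2, 0.3])[: len(covariates)],
        gamma=rngless_gamma,
        sigma=1.0,
        plan=plan,
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _parse_pool(truth: SyntheticTruth) -> list[TreatmentCombination]:
    from .datamodel import parse_combination

    return [parse_combination(lbl, truth.catalog) for lbl in truth.plan.pool]


def _draw_study_arms(
    rng: np.random.Generator, pool: list[TreatmentCombination], k: int, catalog
) -> list[TreatmentCombination]:
    idx = rng.choice(len(pool), size=k, replace=False)
    arms = [pool[i] for i in idx]
    arms.sort(key=lambda c: c.canonical(catalog))
    return arms


def _study_deltas(
    rng: np.random.Generator, truth: SyntheticTruth, arms
) -> np.ndarray:
    """Random contrasts of the non-reference arms vs arms[0]."""
    theta = np.array([truth.combination_effect(c) for c in arms])
    mean = theta[1:] - theta[0]
    cov = multiarm_re_covariance(truth.tau**2, len(arms))
    return rng.multivariate_normal(mean, cov) if len(mean) > 1 else np.array(
        [rng.normal(mean[0], truth.tau)]
    )


def simulate_ad(truth: SyntheticTruth, seed: int) -> NetworkDataset:
    """Simulate an aggregate-data network according to the plan.

    Contrast level: y_i ~ N(delta_i, s_i^2) with delta_i drawn around the
    true combination contrasts with heterogeneity tau.  Arm level: binomial
    counts (logit link) or normal arm means around a random study baseline.
    """
    plan = truth.plan
    if plan is None:
        raise DataError("truth carries no simulation plan")
    rng = np.random.default_rng(seed)
    pool = _parse_pool(truth)
    cat = truth.catalog
    ks = [2] * plan.n_two_arm + [3] * plan.n_three_arm
    contrast_studies: list[ADContrastStudy] = []
    arm_studies: list[ADArmStudy] = []
    for i, k in enumerate(ks):
        arms = _draw_study_arms(rng, pool, k, cat)
        delta = _study_deltas(rng, truth, arms)
        sid = f"s{i + 1:03d}"
        if plan.likelihood == "contrast":
            se = rng.uniform(*plan.se_range, size=k - 1)
            y = delta + se * rng.standard_normal(k - 1)
            study_arms = [(arms[0], None, None)] + [
                (c, float(yv), float(s)) for c, yv, s in zip(arms[1:], y, se)
            ]
            contrast_studies.append(ADContrastStudy(sid, study_arms, scale="MD"))
        else:
            mu = rng.normal(plan.baseline_mean, plan.baseline_sd)
            lin = mu + np.concatenate([[0.0], delta])
            if plan.likelihood == "arm-binomial":
                p = 1.0 / (1.0 + np.exp(-lin))
                r = rng.binomial(plan.arm_size, p)
                arm_studies.append(
                    ADArmStudy(
                        sid,
                        [(c, int(rv), plan.arm_size) for c, rv in zip(arms, r)],
                        binary=True,
                    )
                )
            else:
                means = lin + plan.arm_sd * rng.standard_normal(k) / np.sqrt(
                    plan.arm_size
                )
                arm_studies.append(
                    ADArmStudy(
                        sid,
                        [
                            (c, float(m), plan.arm_sd, plan.arm_size)
                            for c, m in zip(arms, means)
                        ],
                        binary=False,
                    )
                )
    return NetworkDataset(
        catalog=cat, ad_contrast=contrast_studies, ad_arm=arm_studies
    )


def simulate_ipd(truth: SyntheticTruth, seed: int) -> NetworkDataset:
    """Simulate a joint dataset: AD studies plus IPD studies with covariates.

    Patient outcomes follow the one-stage model: study intercept +
    prognostic effects beta + component-covariate effect modification gamma
    + the arm's random contrast, with within-study noise sigma.  Covariates
    are drawn per the plan (standard normal / Bernoulli(0.5)) and centered
    afterwards at their pooled IPD means, which are recorded on the
    dataset.
    """
    plan = truth.plan
    if plan is None:
        raise DataError("truth carries no simulation plan")
    if not plan.covariates:
        raise DataError("IPD simulation needs covariate distributions in the plan")
    rng = np.random.default_rng(seed)
    ad = simulate_ad(truth, int(rng.integers(2**31)))
    cat = truth.catalog
    pool = _parse_pool(truth)
    n_cov = len(plan.covariates)
    beta = np.zeros(n_cov) if truth.beta is None else np.asarray(truth.beta, float)
    gamma = (
        np.zeros((len(cat), n_cov))
        if truth.gamma is None
        else np.asarray(truth.gamma, float)
    )
    ipd_studies = []
    for i in range(plan.n_ipd_studies):
        arms = _draw_study_arms(rng, pool, 2, cat)
        delta = _study_deltas(rng, truth, arms)
        alpha_i = rng.normal(plan.alpha_mean, plan.alpha_sd)
        z = {
            0: np.zeros(len(cat)),
            1: arms[1].indicator(cat) - arms[0].indicator(cat),
        }
        offset = {0: 0.0, 1: float(delta[0])}
        patients = []
        for a in (0, 1):
            for _ in range(plan.patients_per_arm):
                x = np.array(
                    [
                        rng.standard_normal()
                        if kind == "normal"
                        else float(rng.integers(2))
                        for kind in plan.covariates
                    ]
                )
                m = alpha_i + beta @ x + z[a] @ gamma @ x + offset[a]
                y = rng.normal(m, truth.sigma)
                patients.append((float(y), arms[a], x))
        ipd_studies.append(IPDStudy(f"ipd{i + 1:02d}", patients))
    # center covariates at the pooled IPD means, as the loader would
    xs = np.array([p[2] for st in ipd_studies for p in st.patients])
    means = xs.mean(axis=0) if len(xs) else np.zeros(n_cov)
    for st in ipd_studies:
        st.patients = [(y, c, x - means) for y, c, x in st.patients]
    names = tuple(f"x{j + 1}" for j in range(n_cov))
    return NetworkDataset(
        catalog=cat,
        ad_contrast=ad.ad_contrast,
        ad_arm=ad.ad_arm,
        ipd=ipd_studies,
        covariate_names=names,
        covariate_means=means,
    )


# ---------------------------------------------------------------------------
# Operating characteristics of interaction selection
# ---------------------------------------------------------------------------


def selection_operating_characteristics(
    fits: list[PosteriorDraws],
    truth: SyntheticTruth,
    threshold: float = 0.5,
) -> dict:
    """Sensitivity/specificity of interaction detection over replicate fits.

    A pair is flagged when its posterior inclusion frequency exceeds the
    threshold (SSVS fits) or when its 95% credible interval excludes zero
    (LASSO fits).  Truth: pairs with a non-zero generating coefficient.
    Undefined rates (no positives or no negatives in truth) are NaN.
    """
    tp = fp = tn = fn = 0
    for fit in fits:
        if "I_pairs" in fit.params:
            summ = ssvs_inclusion_summary(fit)
            flagged = {
                tuple(pair.split(".")): freq > threshold
                for pair, freq in zip(summ["pair"], summ["inclusion_frequency"])
            }
        elif "d_pairs" in fit.params:
            dp = fit.stacked("d_pairs")
            lo, hi = np.percentile(dp, [2.5, 97.5], axis=0)
            flagged = {
                tuple(lbl.split(".")): bool(l > 0 or h < 0)
                for lbl, l, h in zip(fit.coords["d_pairs"], lo, hi)
            }
        else:
            raise DataError("fit has no interaction draws")
        for pair, hit in flagged.items():
            is_true = abs(truth.d_pairs.get(tuple(sorted(pair)), 0.0)) > 0
            if is_true and hit:
                tp += 1
            elif is_true:
                fn += 1
            elif hit:
                fp += 1
            else:
                tn += 1
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "threshold": threshold,
        "n_replicates": len(fits),
    }
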