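"""MCMC infrastructure shared by the AD and IPD samplers.

The model family is sampled by conjugate Gibbs steps wherever the full
conditional is Gaussian (component effects, study baselines, random
effects, regression coefficients) combined with adaptive random-walk
Metropolis steps for the non-conjugate scalars (heterogeneity tau, spike
scale eta, LASSO rate lambda, within-study sigma) and Gibbs updates for
spike-and-slab indicators and LASSO local scales.  Proposal scales adapt
toward an acceptance rate of ~0.44 during burn-in only, so the kept chain
is a valid time-homogeneous Markov chain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MCMCSettings", "PosteriorDraws", "AdaptiveScale", "sample_mvn_from_precision",
           "sample_inverse_gaussian", "split_rhat", "effective_sample_size"]


@dataclass(frozen=True)
class MCMCSettings:
    """Run settings: chains, kept iterations per chain, burn-in, seed.

    The seed is mandatory; each chain runs on an independent child stream
    of ``numpy.random.default_rng(seed)`` so runs are reproducible
    bit-for-bit.
    """

    seed: int
    chains: int = 4
    iterations: int = 30_000
    burnin: int = 10_000
    thin: int = 1

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        if self.chains < 1 or self.iterations < 1 or self.burnin < 0 or self.thin < 1:
            raise ValueError("invalid MCMC settings")

    def chain_rngs(self) -> list[np.random.Generator]:
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(s) for s in ss.spawn(self.chains)]


class AdaptiveScale:
    """Vector of random-walk proposal scales with Robbins-Monro adaptation.

    Adapts only while ``adapting`` is True (burn-in); target acceptance
    0.44, the scalar-update optimum.
    """

    def __init__(self, n: int, init: float = 0.5, target: float = 0.44):
        self.log_s = np.full(n, math.log(init))
        self.target = target
        self.t = 0
        self.adapting = True

    @property
    def scales(self) -> np.ndarray:
        return np.exp(self.log_s)

    def update(self, accepted: np.ndarray) -> None:
        if not self.adapting:
            return
        self.t += 1
        step = 1.0 / math.sqrt(10 + self.t)
        self.log_s += step * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_s, -10.0, 5.0, out=self.log_s)


def sample_mvn_from_precision(
    rng: np.random.Generator, precision: np.ndarray, linear: np.ndarray
) -> np.ndarray:
    """Draw from N(A^{-1} b, A^{-1}) given precision A and linear term b."""
    chol = np.linalg.cholesky(precision)
    mean = np.linalg.solve(precision, linear)  # cho_solve equivalent
    z = rng.standard_normal(len(linear))
    return mean + np.linalg.solve(chol.T, z)


def sample_inverse_gaussian(
    rng: np.random.Generator, mu: np.ndarray, lam: float | np.ndarray
) -> np.ndarray:
    """Vectorized inverse-Gaussian draws (Michael-Schucany-Haas)."""
    mu = np.asarray(mu, dtype=float)
    nu = rng.standard_normal(mu.shape)
    y = nu**2
    x = mu + mu**2 * y / (2 * lam) - mu / (2 * lam) * np.sqrt(
        4 * mu * lam * y + mu**2 * y**2
    )
    u = rng.uniform(size=mu.shape)
    out = np.where(u <= mu / (mu + x), x, mu**2 / np.maximum(x, 1e-300))
    return np.maximum(out, 1e-300)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape (chains, iterations).  Chains are split in half;
    R-hat is sqrt of (pooled variance / mean within variance).  Degenerate
    (zero-variance) draws give 1 by convention.
    """
    c, n = draws.shape
    half = n // 2
    if half < 2:
        return float("nan")
    if np.allclose(draws, draws.flat[0]):
        return 1.0
    halves = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, k = halves.shape
    within = halves.var(axis=1, ddof=1).mean()
    between = k * halves.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    if within == 0:
        return 1.0
    var_pooled = (k - 1) / k * within + between / k
    return float(np.sqrt(var_pooled / within))


def effective_sample_size(draws: np.ndarray) -> float:
    """Bulk effective sample size via arviz; degenerate draws count fully."""
    import arviz as az

    if np.allclose(draws, draws.flat[0]):
        return float(draws.size)
    return float(az.ess(np.asarray(draws)))


# ---------------------------------------------------------------------------
# Posterior draws container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Labelled MCMC draws for one fitted model.

    ``params`` maps block names ("d", "d_pairs", "I_pairs", "tau", "mu",
    "alpha", "beta", "gamma", "sigma", "lambda", "eta", ...) to arrays of
    shape (chains, iterations) or (chains, iterations, dim); ``coords``
    gives labels for the trailing dimension.  ``design`` retains the
    combination/contrast structure so relative effects and estimability
    flags can be computed downstream; ``meta`` records seed, iteration
    counts, scale, and convergence diagnostics.
    """

    params: dict[str, np.ndarray]
    coords: dict[str, list[str]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    design: object | None = None  # CombinationMatrix
    scale: str = "MD"
    covariate_names: tuple[str, ...] = ()
    covariate_means: np.ndarray | None = None

    def __post_init__(self):
        shapes = {v.shape[:2] for v in self.params.values()}
        if len(shapes) > 1:
            raise ValueError(f"parameter blocks disagree on chain/iteration shape: {shapes}")

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_iterations(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled over chains: (chains*iterations, ...) array."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def scalar_series(self) -> dict[str, np.ndarray]:
        """Flatten every block into named scalar series of (chains, iters)."""
        out = {}
        for name, arr in self.params.items():
            if arr.ndim == 2:
                out[name] = arr
            else:
                labels = self.coords.get(name) or [str(j) for j in range(arr.shape[2])]
                for j, lab in enumerate(labels):
                    out[f"{name}[{lab}]"] = arr[:, :, j]
        return out

    def diagnostics(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.scalar_series().items():
            rows.append(
                {
                    "parameter": name,
                    "rhat": split_rhat(arr),
                    "ess": effective_sample_size(arr),
                }
            )
        return pd.DataFrame(rows)

    # -- persistence (tidy table + JSON metadata) ---------------------------

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for name, arr in self.scalar_series().items():
            c, n = arr.shape
            recs.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), n),
                        "iteration": np.tile(np.arange(n), c),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "draws.csv", index=False)
        meta = dict(self.meta)
        meta["scale"] = self.scale
        meta["covariate_names"] = list(self.covariate_names)
        if self.covariate_means is not None:
            meta["covariate_means"] = np.asarray(self.covariate_means).tolist()
        meta["coords"] = {k: list(v) for k, v in self.coords.items()}
        if self.design is not None:
            meta["design"] = {
                "codes": list(self.design.catalog.codes),
                "pairs": [list(p) for p in self.design.interactions.pairs],
                "contrast_rows": self.design.contrast_rows.tolist(),
                "combinations": [
                    sorted(c.members) for c in self.design.combinations
                ],
            }
        with open(outdir / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=1, default=str)

    @classmethod
    def load(cls, outdir: str | Path) -> "PosteriorDraws":
        from .datamodel import ComponentCatalog, TreatmentCombination
        from .design import CombinationMatrix, InteractionSet

        outdir = Path(outdir)
        df = pd.read_csv(outdir / "draws.csv")
        with open(outdir / "metadata.json") as fh:
            meta = json.load(fh)
        coords = {k: list(v) for k, v in meta.pop("coords", {}).items()}
        n_chains = int(df["chain"].max()) + 1
        n_iter = int(df["iteration"].max()) + 1
        series: dict[str, np.ndarray] = {}
        for name, grp in df.groupby("parameter", sort=False):
            series[name] = grp["value"].to_numpy().reshape(n_chains, n_iter)
        params: dict[str, np.ndarray] = {}
        for block, labels in coords.items():
            arrs = [series.pop(f"{block}[{lab}]") for lab in labels]
            params[block] = np.stack(arrs, axis=-1)
        params.update(series)
        design = None
        dmeta = meta.pop("design", None)
        if dmeta is not None:
            cat = ComponentCatalog(tuple(dmeta["codes"]))
            inter = InteractionSet(pairs=tuple(tuple(p) for p in dmeta["pairs"]))
            combos = [TreatmentCombination(frozenset(m)) for m in dmeta["combinations"]]
            membership = np.array(
                [
                    np.concatenate(
                        [c.indicator(cat)]
                        + ([np.array([1.0 if (p in c.members and q in c.members) else 0.0
                                      for p, q in inter.pairs])] if len(inter) else [])
                    )
                    for c in combos
                ]
            )
            design = CombinationMatrix(
                catalog=cat,
                interactions=inter,
                combinations=combos,
                membership=membership,
                contrast_rows=np.array(dmeta["contrast_rows"]),
                row_study=[],
                zero_pairs=[],
            )
        means = meta.pop("covariate_means", None)
        return cls(
            params=params,
            coords=coords,
            meta=meta,
            design=design,
            scale=meta.pop("scale", "MD"),
            covariate_names=tuple(meta.pop("covariate_names", ())),
            covariate_means=np.asarray(means) if means is not None else None,
        )
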