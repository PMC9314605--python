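"""Posterior summaries and relative-effect prediction between combinations.

Given posterior draws of the component effects d (and any admitted pair
interactions, and effect-modification coefficients gamma), the relative
effect of combination A vs B for a patient with centered covariate profile
x is computed draw by draw:

    effect = sum_{q in A} d_q - sum_{q in B} d_q
             + sum_{pairs in A} d_pair - sum_{pairs in B} d_pair
             + (sum_{q in A} gamma_q - sum_{q in B} gamma_q)' x

and exponentiated when an odds-ratio scale is requested for a log-odds
fit.  Positive values (OR > 1) favour A over B on the outcome's natural
direction — which is "more events" for a binary outcome and "higher score"
for a continuous one, so interpretation depends on whether the outcome is
desirable (remission) or adverse (symptom score).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DataError, TreatmentCombination, parse_combination
from .design import contrast_design_row
from .mcmc import PosteriorDraws, effective_sample_size, split_rhat

__all__ = ["RelativeEffectEstimate", "summarize", "relative_effect", "prediction_table"]


@dataclass
class RelativeEffectEstimate:
    """A summarized A-vs-B relative effect on a stated scale."""

    comparison: tuple[str, str]
    scale: str
    mean: float
    median: float
    ci_low: float
    ci_high: float
    covariate_profile: dict[str, float] | None
    estimable: bool

    def __post_init__(self):
        if self.ci_low > self.ci_high:
            raise ValueError("credible interval bounds out of order")

    @property
    def warning(self) -> str | None:
        if not self.estimable:
            return (
                "contrast lies outside the design's row space: the posterior "
                "in this direction is driven by the prior"
            )
        return None

    def as_dict(self) -> dict:
        return {
            "comparison": f"({self.comparison[0]}) vs ({self.comparison[1]})",
            "scale": self.scale,
            "mean": self.mean,
            "median": self.median,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "estimable": self.estimable,
        }


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """One row per scalar parameter: mean, median, SD, 95% CrI, R-hat, ESS."""
    rows = []
    for name, arr in draws.scalar_series().items():
        flat = arr.reshape(-1)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "median": float(np.median(flat)),
                "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "rhat": split_rhat(arr),
                "ess": effective_sample_size(arr),
            }
        )
    return pd.DataFrame(rows)


def _as_combo(combo, design) -> TreatmentCombination:
    if isinstance(combo, TreatmentCombination):
        for c in combo.members:
            if c not in design.catalog:
                raise DataError(f"unknown component {c!r}")
        return combo
    return parse_combination(str(combo), design.catalog)


def _effect_draws(
    draws: PosteriorDraws,
    combo_a: TreatmentCombination,
    combo_b: TreatmentCombination,
    profile_x: np.ndarray | None,
) -> np.ndarray:
    design = draws.design
    row = contrast_design_row(combo_b, combo_a, design.catalog, design.interactions)
    d = draws.stacked("d")
    eff = d @ row[: design.n_main]
    if len(design.interactions) and "d_pairs" in draws.params:
        eff = eff + draws.stacked("d_pairs") @ row[design.n_main :]
    if profile_x is not None and "gamma" in draws.params:
        g = draws.stacked("gamma").reshape(
            -1, design.n_main, len(draws.covariate_names)
        )
        zmain = row[: design.n_main]
        eff = eff + np.einsum("nqc,q,c->n", g, zmain, profile_x)
    return eff


def relative_effect(
    draws: PosteriorDraws,
    combo_a,
    combo_b,
    covariate_profile: dict[str, float] | None = None,
    scale: str | None = None,
) -> RelativeEffectEstimate:
    """Posterior relative effect of combination A vs B.

    ``covariate_profile`` maps covariate names to raw (uncentered) values;
    it is centered by the means recorded at load time.  ``scale`` defaults
    to the fit's own scale; requesting ``"OR"`` (or RR/HR) on a log-scale
    fit exponentiates draw by draw.  Inestimable contrasts are still
    summarized but flagged, since their posterior is prior-driven.
    """
    if draws.design is None:
        raise DataError("draws carry no design; cannot form relative effects")
    a = _as_combo(combo_a, draws.design)
    b = _as_combo(combo_b, draws.design)
    profile_x = None
    prof_used = None
    if covariate_profile is not None:
        names = list(draws.covariate_names)
        unknown = set(covariate_profile) - set(names)
        if unknown:
            raise DataError(f"unknown covariates in profile: {sorted(unknown)}")
        raw = np.array([covariate_profile.get(n, np.nan) for n in names], float)
        if np.isnan(raw).any():
            missing = [n for n, v in zip(names, raw) if np.isnan(v)]
            raise DataError(f"profile is missing covariates: {missing}")
        means = (
            draws.covariate_means
            if draws.covariate_means is not None
            else np.zeros(len(names))
        )
        profile_x = raw - means
        prof_used = dict(covariate_profile)
    eff = _effect_draws(draws, a, b, profile_x)

    from .design import estimability

    report = estimability(draws.design, queries=[(a, b)])
    estimable = bool(report.query_estimable[0])

    out_scale = scale or draws.scale
    log_scales = {"logOR": "OR", "logRR": "RR", "logHR": "HR"}
    if out_scale in ("OR", "RR", "HR"):
        if draws.scale not in log_scales or log_scales[draws.scale] != out_scale:
            raise DataError(
                f"cannot report {out_scale} from a fit on scale {draws.scale!r}"
            )
        eff = np.exp(eff)
    lo, hi = np.percentile(eff, [2.5, 97.5])
    cat = draws.design.catalog
    return RelativeEffectEstimate(
        comparison=(a.canonical(cat), b.canonical(cat)),
        scale=out_scale,
        mean=float(eff.mean()),
        median=float(np.median(eff)),
        ci_low=float(lo),
        ci_high=float(hi),
        covariate_profile=prof_used,
        estimable=estimable,
    )


def prediction_table(
    draws: PosteriorDraws,
    profiles: list[dict[str, float] | None],
    comparisons: list[tuple],
    scale: str | None = None,
) -> pd.DataFrame:
    """Cross-product of covariate profiles and comparisons, one row each."""
    rows = []
    for k, prof in enumerate(profiles):
        for a, b in comparisons:
            est = relative_effect(draws, a, b, covariate_profile=prof, scale=scale)
            rec = est.as_dict()
            rec["profile"] = k
            rows.append(rec)
    cols = [
        "profile", "comparison", "scale", "mean", "median",
        "ci_low", "ci_high", "estimable",
    ]
    return pd.DataFrame(rows, columns=cols if rows else None)
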