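"""Combination-to-component design matrices and estimability diagnostics.

Under additivity the effect of combination ``T`` is ``theta_T = sum_{q in T}
d_q``; with two-way interactions, ``+ sum_{(p,q) subset T} d_{p.q}``.  A
study contrasting Y against X therefore contributes a signed design row
whose entry for component q is +1 if q is in Y only, -1 if in X only, and 0
otherwise, with interaction columns treated analogously on pair membership.

Whether an individual ``d`` is determined by the data is a property of the
stacked contrast rows: a parameter direction in the null space of that
matrix is inestimable (its posterior equals its prior), while any contrast
whose design row lies in the row space is estimable — in particular every
comparison actually made inside a study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    ComponentCatalog,
    DataError,
    NetworkDataset,
    TreatmentCombination,
)

__all__ = [
    "InteractionSet",
    "CombinationMatrix",
    "EstimabilityReport",
    "contrast_design_row",
    "build_design",
    "estimability",
    "all_pairs",
]

RANK_RTOL = 1e-8  # singular values below RANK_RTOL * s_max count as zero


@dataclass(frozen=True)
class InteractionSet:
    """Unordered component pairs admitted to an interaction model.

    ``prior_inclusion`` carries the per-pair prior probability that the
    interaction enters the model (used by spike-and-slab selection);
    pairs not listed in it default to ``default_inclusion``.
    """

    pairs: tuple[tuple[str, str], ...] = ()
    prior_inclusion: dict[tuple[str, str], float] = field(default_factory=dict)
    default_inclusion: float = 0.5

    def __post_init__(self) -> None:
        norm = []
        seen = set()
        for p, q in self.pairs:
            p, q = sorted((p.strip().lower(), q.strip().lower()))
            if p == q:
                raise DataError(f"interaction pair ({p},{q}) repeats a component")
            if (p, q) in seen:
                raise DataError(f"duplicate interaction pair ({p},{q})")
            seen.add((p, q))
            norm.append((p, q))
        object.__setattr__(self, "pairs", tuple(norm))
        probs = {}
        for key, pr in self.prior_inclusion.items():
            k = tuple(sorted(c.strip().lower() for c in key))
            if not 0 < pr < 1:
                raise DataError(f"prior inclusion for {k} must be in (0,1)")
            probs[k] = float(pr)
        object.__setattr__(self, "prior_inclusion", probs)
        if not 0 < self.default_inclusion < 1:
            raise DataError("default inclusion probability must be in (0,1)")

    def validate_against(self, catalog: ComponentCatalog) -> None:
        for p, q in self.pairs:
            for c in (p, q):
                if c not in catalog:
                    raise DataError(f"interaction pair references unknown component {c!r}")

    def inclusion_prob(self, pair: tuple[str, str]) -> float:
        return self.prior_inclusion.get(tuple(sorted(pair)), self.default_inclusion)

    def __len__(self) -> int:
        return len(self.pairs)


def all_pairs(catalog: ComponentCatalog, default_inclusion: float = 0.5) -> InteractionSet:
    """Every two-way pair of catalog components, equiprobable a priori."""
    codes = catalog.codes
    pairs = tuple(
        (codes[i], codes[j]) for i in range(len(codes)) for j in range(i + 1, len(codes))
    )
    return InteractionSet(pairs=pairs, default_inclusion=default_inclusion)


def _pair_indicator(combo: TreatmentCombination, pairs) -> np.ndarray:
    return np.array(
        [1.0 if (p in combo.members and q in combo.members) else 0.0 for p, q in pairs]
    )


def contrast_design_row(
    combo_x: TreatmentCombination,
    combo_y: TreatmentCombination,
    catalog: ComponentCatalog,
    interactions: InteractionSet | None = None,
) -> np.ndarray:
    """Signed coefficient vector of the Y-vs-X contrast.

    Entry q is +1 if component q belongs to Y only, -1 if to X only, 0 if to
    both or neither; interaction entries are the same difference of pair
    memberships.  Antisymmetric in (X, Y) and additive along chains:
    row(X,Z) = row(X,Y) + row(Y,Z).
    """
    main = combo_y.indicator(catalog) - combo_x.indicator(catalog)
    if interactions is None or not len(interactions):
        return main
    inter = _pair_indicator(combo_y, interactions.pairs) - _pair_indicator(
        combo_x, interactions.pairs
    )
    return np.concatenate([main, inter])


@dataclass
class CombinationMatrix:
    """Membership matrix of distinct combinations plus stacked contrast rows.

    ``membership`` has one 0/1 row per distinct combination over main (and
    optional pair) columns.  ``contrast_rows`` stacks one signed design row
    per non-reference arm per study; ``row_study`` maps each row to its
    study id.  ``zero_pairs`` lists admitted pairs whose components never
    co-occur in any arm (their column is identically zero).
    """

    catalog: ComponentCatalog
    interactions: InteractionSet
    combinations: list[TreatmentCombination]
    membership: np.ndarray
    contrast_rows: np.ndarray
    row_study: list[str]
    zero_pairs: list[tuple[str, str]]

    @property
    def n_main(self) -> int:
        return len(self.catalog)

    @property
    def column_labels(self) -> list[str]:
        return list(self.catalog.codes) + [f"{p}.{q}" for p, q in self.interactions.pairs]

    def membership_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.membership,
            index=[c.canonical(self.catalog) for c in self.combinations],
            columns=self.column_labels,
        )


def build_design(
    dataset: NetworkDataset, interactions: InteractionSet | None = None
) -> CombinationMatrix:
    """Assemble membership and per-study contrast rows for a dataset.

    Produces one contrast row per non-reference arm per study, i.e.
    ``sum_i (k_i - 1)`` rows over ``N_components + n_pairs`` columns.
    """
    inter = interactions if interactions is not None else InteractionSet()
    inter.validate_against(dataset.catalog)
    cat = dataset.catalog
    combos = dataset.all_combinations()
    membership = np.array(
        [
            np.concatenate([c.indicator(cat), _pair_indicator(c, inter.pairs)])
            if len(inter)
            else c.indicator(cat)
            for c in combos
        ]
    )
    rows = []
    row_study = []
    from .datamodel import _study_arm_combos  # study-order arm lists

    study_ids = (
        [st.study_id for st in dataset.ad_contrast]
        + [st.study_id for st in dataset.ad_arm]
        + [st.study_id for st in dataset.ipd]
    )
    for sid, arms in zip(study_ids, _study_arm_combos(dataset)):
        ref = arms[0]
        for combo in arms[1:]:
            rows.append(contrast_design_row(ref, combo, cat, inter))
            row_study.append(sid)
    contrast_rows = np.array(rows) if rows else np.zeros((0, membership.shape[1]))
    zero_pairs = []
    if len(inter):
        pair_cols = membership[:, len(cat):]
        for j, pair in enumerate(inter.pairs):
            if not pair_cols[:, j].any():
                zero_pairs.append(pair)
    return CombinationMatrix(
        catalog=cat,
        interactions=inter,
        combinations=combos,
        membership=membership,
        contrast_rows=contrast_rows,
        row_study=row_study,
        zero_pairs=zero_pairs,
    )


@dataclass
class EstimabilityReport:
    """Rank, inestimable directions, and per-query estimability flags."""

    rank: int
    n_params: int
    null_space: np.ndarray           # (n_params, n_null) orthonormal basis
    column_labels: list[str]
    queries: list[tuple[str, str]]
    query_estimable: list[bool]
    query_residual: list[float]

    @property
    def fully_identified(self) -> bool:
        return self.rank == self.n_params

    def inestimable_directions(self) -> pd.DataFrame:
        """Null-space basis labelled by components/pairs (columns = directions)."""
        return pd.DataFrame(
            self.null_space,
            index=self.column_labels,
            columns=[f"dir{j}" for j in range(self.null_space.shape[1])],
        )

    def flat_parameters(self, tol: float = 1e-8) -> list[str]:
        """Parameters with any loading on an inestimable direction."""
        if self.null_space.shape[1] == 0:
            return []
        load = np.abs(self.null_space).max(axis=1)
        return [lab for lab, l in zip(self.column_labels, load) if l > tol]


def estimability(
    design: CombinationMatrix,
    queries: list[tuple[TreatmentCombination, TreatmentCombination]] | None = None,
) -> EstimabilityReport:
    """Rank/null-space analysis of the stacked contrast rows.

    The numerical rank uses an SVD with singular values below
    ``RANK_RTOL * s_max`` treated as zero (design entries are 0/±1 so the
    scale is benign).  A query contrast X-vs-Y is estimable iff its design
    row lies in the row space, judged by the relative residual of its
    projection.
    """
    X = design.contrast_rows
    p = X.shape[1]
    if X.size == 0:
        rank, null = 0, np.eye(p)
        vt = np.zeros((0, p))
    else:
        u, s, vt = np.linalg.svd(X, full_matrices=True)
        tol = RANK_RTOL * (s.max() if s.size else 1.0)
        rank = int((s > tol).sum())
        null = vt[rank:].T
    labels = design.column_labels
    q_est, q_res, q_lab = [], [], []
    if queries:
        row_basis = vt[:rank]  # orthonormal
        for a, b in queries:
            row = contrast_design_row(b, a, design.catalog, design.interactions)
            norm = np.linalg.norm(row)
            if norm == 0:
                resid = 0.0
            else:
                proj = row_basis.T @ (row_basis @ row)
                resid = float(np.linalg.norm(row - proj) / norm)
            q_lab.append(
                (a.canonical(design.catalog), b.canonical(design.catalog))
            )
            q_res.append(resid)
            q_est.append(resid < 1e-6)
    return EstimabilityReport(
        rank=rank,
        n_params=p,
        null_space=null,
        column_labels=labels,
        queries=q_lab,
        query_estimable=q_est,
        query_residual=q_res,
    )
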