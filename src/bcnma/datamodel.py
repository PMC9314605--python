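"""Data model for component-network evidence and CSV readers.

Three kinds of evidence are supported, mirroring how trial data arrive in
practice:

* **contrast level** — a study reports a relative effect ``y`` (mean
  difference, log odds ratio, ...) with its standard error against a
  reference arm;
* **arm level** — a study reports per-arm summaries, either events/size for
  a binary outcome or mean/SD/size for a continuous one, optionally with
  study-mean covariates for meta-regression;
* **IPD** — one row per randomized patient with outcome, assigned
  combination, and covariates (pre-imputed; no missing values).

Treatment arms are labelled by "+"-separated component codes, e.g.
``"pl + ftf + pe"``.  Codes are case-insensitive on input and stored
lower-case; the catalog order fixes the canonical order of every
combination string and every design-matrix column, so results are
reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "ComponentCatalog",
    "TreatmentCombination",
    "ADContrastStudy",
    "ADArmStudy",
    "IPDStudy",
    "NetworkDataset",
    "ValidationReport",
    "parse_combination",
    "read_dataset",
    "write_dataset",
    "validate_network",
]

SCALES = ("MD", "SMD", "logOR", "logRR", "logHR")


class DataError(ValueError):
    """Raised when input data violate the documented schemas."""


@dataclass(frozen=True)
class ComponentCatalog:
    """Ordered registry of component codes.

    The order given at construction is the canonical order used for design
    matrix columns and for the canonical string form of combinations.
    """

    codes: tuple[str, ...]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = tuple(c.strip().lower() for c in self.codes)
        if not norm:
            raise DataError("component catalog is empty")
        if any(not c for c in norm):
            raise DataError("component catalog contains an empty code")
        if len(set(norm)) != len(norm):
            dupes = sorted({c for c in norm if norm.count(c) > 1})
            raise DataError(f"duplicate component codes in catalog: {dupes}")
        object.__setattr__(self, "codes", norm)

    def index(self, code: str) -> int:
        return self.codes.index(code.strip().lower())

    def __contains__(self, code: str) -> bool:
        return code.strip().lower() in self.codes

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class TreatmentCombination:
    """A set of components given together, e.g. {pl, ftf, pe}."""

    members: frozenset[str]

    def canonical(self, catalog: ComponentCatalog) -> str:
        """Catalog-ordered "+"-joined label, the canonical string form."""
        return " + ".join(c for c in catalog.codes if c in self.members)

    def indicator(self, catalog: ComponentCatalog) -> np.ndarray:
        """0/1 membership vector in catalog order."""
        return np.array([1.0 if c in self.members else 0.0 for c in catalog.codes])

    def __len__(self) -> int:
        return len(self.members)


def parse_combination(label: str, catalog: ComponentCatalog) -> TreatmentCombination:
    """Parse a "+"-separated combination label against the catalog.

    Whitespace-insensitive and case-insensitive.  Unknown or duplicated
    codes are rejected with the offending token named.
    """
    if label is None or not str(label).strip():
        raise DataError("empty combination label")
    tokens = [t.strip().lower() for t in str(label).split("+")]
    if any(not t for t in tokens):
        raise DataError(f"malformed combination label {label!r}")
    seen: set[str] = set()
    for tok in tokens:
        if tok not in catalog:
            raise DataError(f"unknown component code {tok!r} in label {label!r}")
        if tok in seen:
            raise DataError(f"duplicate component {tok!r} in label {label!r}")
        seen.add(tok)
    return TreatmentCombination(frozenset(seen))


@dataclass
class ADContrastStudy:
    """Aggregate study reporting relative effects vs its first-listed arm.

    ``arms[0]`` is the reference; its ``y``/``se`` are None.  ``ref_se``
    optionally carries the standard error of the reference arm, which
    induces the covariance between contrasts of a multi-arm study.
    """

    study_id: str
    arms: list[tuple[TreatmentCombination, float | None, float | None]]
    scale: str = "MD"
    ref_se: float | None = None
    covariate_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise DataError(f"study {self.study_id}: unknown scale {self.scale!r}")
        if len(self.arms) < 2:
            raise DataError(f"study {self.study_id}: needs >=1 non-reference arm")
        combos = [a[0].members for a in self.arms]
        if len({frozenset(c) for c in combos}) != len(combos):
            raise DataError(f"study {self.study_id}: duplicate combinations")
        for combo, y, se in self.arms[1:]:
            if y is None or se is None:
                raise DataError(f"study {self.study_id}: non-reference arm missing y/se")
            if not np.isfinite(y):
                raise DataError(f"study {self.study_id}: non-finite y")
            if not (np.isfinite(se) and se > 0):
                raise DataError(f"study {self.study_id}: se must be > 0")

    @property
    def n_arms(self) -> int:
        return len(self.arms)


@dataclass
class ADArmStudy:
    """Aggregate study with per-arm summaries.

    Binary arms are (combination, r, n); continuous arms are
    (combination, mean, sd, n).  ``covariate_means`` holds study-level
    covariate means for AD meta-regression, in registry order.
    """

    study_id: str
    arms: list[tuple]
    binary: bool
    covariate_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise DataError(f"study {self.study_id}: needs >=2 arms")
        combos = [a[0].members for a in self.arms]
        if len({frozenset(c) for c in combos}) != len(combos):
            raise DataError(f"study {self.study_id}: duplicate combinations")
        for arm in self.arms:
            if self.binary:
                _, r, n = arm
                if not (n > 0 and 0 <= r <= n):
                    raise DataError(
                        f"study {self.study_id}: invalid event count r={r}, n={n}"
                    )
            else:
                _, mean, sd, n = arm
                if not (np.isfinite(mean) and sd > 0 and n > 0):
                    raise DataError(
                        f"study {self.study_id}: continuous arm needs sd>0, n>0"
                    )

    @property
    def n_arms(self) -> int:
        return len(self.arms)


@dataclass
class IPDStudy:
    """Individual-patient data: (outcome, combination, covariate vector) rows."""

    study_id: str
    patients: list[tuple[float, TreatmentCombination, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.patients:
            raise DataError(f"study {self.study_id}: no patients")
        lens = {len(np.atleast_1d(p[2])) for p in self.patients}
        if len(lens) > 1:
            raise DataError(f"study {self.study_id}: ragged covariate vectors")
        combos = {p[1].members for p in self.patients}
        if len(combos) < 2:
            raise DataError(
                f"study {self.study_id}: IPD study needs >=2 distinct combinations"
            )
        for y, _, x in self.patients:
            if not np.isfinite(y):
                raise DataError(f"study {self.study_id}: non-finite outcome")
            if not np.all(np.isfinite(np.atleast_1d(x))):
                raise DataError(
                    f"study {self.study_id}: missing covariate values (impute first)"
                )

    @property
    def combinations(self) -> list[TreatmentCombination]:
        seen: dict[frozenset, TreatmentCombination] = {}
        for _, combo, _ in self.patients:
            seen.setdefault(combo.members, combo)
        return list(seen.values())


@dataclass
class NetworkDataset:
    """All evidence about one component network.

    Covariates are stored centered; ``covariate_means`` records the
    constants subtracted so that new-patient profiles can be centered
    consistently at prediction time.  The centering pool is the IPD
    patients (falling back to AD study means when no IPD is present).
    """

    catalog: ComponentCatalog
    ad_contrast: list[ADContrastStudy] = field(default_factory=list)
    ad_arm: list[ADArmStudy] = field(default_factory=list)
    ipd: list[IPDStudy] = field(default_factory=list)
    covariate_names: tuple[str, ...] = ()
    covariate_means: np.ndarray | None = None
    # pre-imputed stacks: imputation id -> IPD study list (ipd holds the first)
    ipd_imputations: dict[int, list[IPDStudy]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ad_contrast or self.ad_arm or self.ipd):
            raise DataError("dataset contains no studies")

    @property
    def n_studies(self) -> int:
        return len(self.ad_contrast) + len(self.ad_arm) + len(self.ipd)

    def load_report(self) -> dict:
        """Counts of studies, arms and patients per evidence type."""
        return {
            "ad_contrast_studies": len(self.ad_contrast),
            "ad_contrast_arms": sum(st.n_arms for st in self.ad_contrast),
            "ad_arm_studies": len(self.ad_arm),
            "ad_arm_arms": sum(st.n_arms for st in self.ad_arm),
            "ipd_studies": len(self.ipd),
            "ipd_patients": sum(len(st.patients) for st in self.ipd),
            "n_imputations": max(len(self.ipd_imputations), 1) if self.ipd else 0,
            "covariates": list(self.covariate_names),
        }

    def all_combinations(self) -> list[TreatmentCombination]:
        """Distinct combinations across all evidence, in canonical order."""
        seen: dict[str, TreatmentCombination] = {}
        for st in self.ad_contrast:
            for arm in st.arms:
                seen.setdefault(arm[0].canonical(self.catalog), arm[0])
        for st in self.ad_arm:
            for arm in st.arms:
                seen.setdefault(arm[0].canonical(self.catalog), arm[0])
        for st in self.ipd:
            for combo in st.combinations:
                seen.setdefault(combo.canonical(self.catalog), combo)
        return [seen[k] for k in sorted(seen)]


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------


def _read_catalog(path: str | Path) -> ComponentCatalog:
    df = pd.read_csv(path, dtype=str)
    if "code" not in df.columns:
        raise DataError(f"{path}: catalog needs a 'code' column")
    desc = {}
    if "description" in df.columns:
        desc = {
            str(c).strip().lower(): str(d)
            for c, d in zip(df["code"], df["description"])
            if pd.notna(d)
        }
    return ComponentCatalog(tuple(str(c) for c in df["code"]), desc)


def _read_ad_contrast(path: str | Path, catalog: ComponentCatalog) -> list[ADContrastStudy]:
    df = pd.read_csv(path)
    required = {"study_id", "arm_label", "y", "se"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    cov_cols = [c for c in df.columns if c.startswith("covmean_")]
    studies = []
    for sid, grp in df.groupby("study_id", sort=False):
        arms: list[tuple] = []
        scale = "MD"
        ref_se = None
        for idx, row in grp.iterrows():
            combo = parse_combination(row["arm_label"], catalog)
            y = row["y"] if pd.notna(row["y"]) else None
            se = row["se"] if pd.notna(row["se"]) else None
            if "scale" in grp.columns and pd.notna(row.get("scale")):
                scale = str(row["scale"])
            if not arms:
                # reference arm: y empty; its se, when given, is the ref-arm SE
                if y is not None:
                    raise DataError(
                        f"{path} row {idx}: reference arm of study {sid} must "
                        "have empty y"
                    )
                ref_se = se
                arms.append((combo, None, None))
            else:
                arms.append((combo, y, se))
        covmeans = (
            grp.iloc[0][cov_cols].to_numpy(dtype=float) if cov_cols else None
        )
        studies.append(
            ADContrastStudy(
                str(sid), arms, scale=scale, ref_se=ref_se, covariate_means=covmeans
            )
        )
    return studies


def _read_ad_arm(path: str | Path, catalog: ComponentCatalog) -> list[ADArmStudy]:
    df = pd.read_csv(path)
    if not {"study_id", "arm_label"} <= set(df.columns):
        raise DataError(f"{path}: missing study_id/arm_label columns")
    binary = "r" in df.columns
    if binary and not {"r", "n"} <= set(df.columns):
        raise DataError(f"{path}: binary arm file needs r and n columns")
    if not binary and not {"mean", "sd", "n"} <= set(df.columns):
        raise DataError(f"{path}: continuous arm file needs mean, sd, n columns")
    cov_cols = [c for c in df.columns if c.startswith("covmean_")]
    studies = []
    for sid, grp in df.groupby("study_id", sort=False):
        arms: list[tuple] = []
        for idx, row in grp.iterrows():
            combo = parse_combination(row["arm_label"], catalog)
            try:
                if binary:
                    arms.append((combo, int(row["r"]), int(row["n"])))
                else:
                    arms.append(
                        (combo, float(row["mean"]), float(row["sd"]), int(row["n"]))
                    )
            except (TypeError, ValueError) as exc:
                raise DataError(f"{path} row {idx}: {exc}") from exc
        covmeans = None
        if cov_cols:
            vals = grp.iloc[0][cov_cols].to_numpy(dtype=float)
            covmeans = vals
        studies.append(ADArmStudy(str(sid), arms, binary=binary, covariate_means=covmeans))
    return studies


def _read_ipd(
    path: str | Path, catalog: ComponentCatalog
) -> tuple[dict[int, list[IPDStudy]], tuple[str, ...]]:
    df = pd.read_csv(path)
    required = {"study_id", "arm_label", "y"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: IPD file needs {sorted(required)} columns")
    reserved = {"study_id", "patient_id", "arm_label", "y", "imputation"}
    cov_names = tuple(c for c in df.columns if c not in reserved)
    has_imp = "imputation" in df.columns
    imp_ids = sorted(df["imputation"].unique()) if has_imp else [1]
    out: dict[int, list[IPDStudy]] = {}
    for m in imp_ids:
        sub = df[df["imputation"] == m] if has_imp else df
        studies = []
        for sid, grp in sub.groupby("study_id", sort=False):
            patients = []
            for _, row in grp.iterrows():
                combo = parse_combination(row["arm_label"], catalog)
                x = row[list(cov_names)].to_numpy(dtype=float) if cov_names else np.zeros(0)
                patients.append((float(row["y"]), combo, x))
            studies.append(IPDStudy(str(sid), patients))
        out[int(m)] = studies
    return out, cov_names


def _center_covariates(
    ipd_by_imp: dict[int, list[IPDStudy]],
    ad_arm: list[ADArmStudy],
    ad_contrast: list[ADContrastStudy],
    n_cov: int,
) -> np.ndarray:
    """Compute centering constants and subtract them in place.

    The pool is all IPD patients of the first imputation; with no IPD, the
    AD study means.  AD study means are centered by the same constants.
    """
    if n_cov == 0:
        return np.zeros(0)
    ad_with_cov = [
        st for st in list(ad_arm) + list(ad_contrast) if st.covariate_means is not None
    ]
    if ipd_by_imp:
        first = next(iter(sorted(ipd_by_imp)))
        xs = np.array([p[2] for st in ipd_by_imp[first] for p in st.patients])
        means = xs.mean(axis=0)
    else:
        xs = np.array([st.covariate_means for st in ad_with_cov])
        means = xs.mean(axis=0) if len(xs) else np.zeros(n_cov)
    for studies in ipd_by_imp.values():
        for st in studies:
            st.patients = [(y, c, np.asarray(x, float) - means) for y, c, x in st.patients]
    for st in ad_with_cov:
        st.covariate_means = np.asarray(st.covariate_means, float) - means
    return means


def read_dataset(
    catalog: str | Path,
    ad_contrast: str | Path | None = None,
    ad_arm: str | Path | None = None,
    ipd: str | Path | None = None,
) -> NetworkDataset:
    """Read and validate the CSV schemas into a :class:`NetworkDataset`.

    Covariates (IPD columns and AD ``covmean_`` columns) are centered by the
    pooled IPD means; the constants are recorded on the dataset.  An
    ``imputation`` column in the IPD file yields per-imputation study stacks
    in ``ipd_imputations`` (with ``ipd`` holding the first).
    """
    cat = _read_catalog(catalog)
    contrast = _read_ad_contrast(ad_contrast, cat) if ad_contrast else []
    arm = _read_ad_arm(ad_arm, cat) if ad_arm else []
    ipd_by_imp: dict[int, list[IPDStudy]] = {}
    cov_names: tuple[str, ...] = ()
    if ipd:
        ipd_by_imp, cov_names = _read_ipd(ipd, cat)
    if not cov_names:
        # AD meta-regression covariates without IPD
        n_ad_cov = next(
            (
                len(st.covariate_means)
                for st in list(arm) + list(contrast)
                if st.covariate_means is not None
            ),
            0,
        )
        cov_names = tuple(f"x{i}" for i in range(n_ad_cov))
    means = _center_covariates(ipd_by_imp, arm, contrast, len(cov_names))
    first_ipd = ipd_by_imp[min(ipd_by_imp)] if ipd_by_imp else []
    return NetworkDataset(
        catalog=cat,
        ad_contrast=contrast,
        ad_arm=arm,
        ipd=first_ipd,
        covariate_names=cov_names,
        covariate_means=means if len(cov_names) else None,
        ipd_imputations=ipd_by_imp,
    )


def write_dataset(dataset: NetworkDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset back to the CSV schemas; inverse of :func:`read_dataset`.

    Covariates are written as stored (centered), with the recorded means in
    ``covariate_means.csv`` so a round trip reproduces the dataset exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cat = dataset.catalog
    paths: dict[str, Path] = {}
    paths["catalog"] = outdir / "catalog.csv"
    pd.DataFrame(
        {
            "code": cat.codes,
            "description": [cat.descriptions.get(c, "") for c in cat.codes],
        }
    ).to_csv(paths["catalog"], index=False)
    if dataset.ad_contrast:
        rows = []
        for st in dataset.ad_contrast:
            for j, (combo, y, se) in enumerate(st.arms):
                row = {
                    "study_id": st.study_id,
                    "arm_label": combo.canonical(cat),
                    "y": "" if y is None else y,
                    "se": (st.ref_se if j == 0 else se) or "",
                    "scale": st.scale,
                }
                if st.covariate_means is not None:
                    for name, v in zip(dataset.covariate_names, st.covariate_means):
                        row[f"covmean_{name}"] = v
                rows.append(row)
        paths["ad_contrast"] = outdir / "ad_contrast.csv"
        pd.DataFrame(rows).to_csv(paths["ad_contrast"], index=False)
    if dataset.ad_arm:
        rows = []
        for st in dataset.ad_arm:
            for arm in st.arms:
                row = {"study_id": st.study_id, "arm_label": arm[0].canonical(cat)}
                if st.binary:
                    row.update(r=arm[1], n=arm[2])
                else:
                    row.update(mean=arm[1], sd=arm[2], n=arm[3])
                if st.covariate_means is not None:
                    for name, v in zip(dataset.covariate_names, st.covariate_means):
                        row[f"covmean_{name}"] = v
                rows.append(row)
        paths["ad_arm"] = outdir / "ad_arm.csv"
        pd.DataFrame(rows).to_csv(paths["ad_arm"], index=False)
    if dataset.ipd:
        rows = []
        imps = dataset.ipd_imputations or {1: dataset.ipd}
        for m, studies in sorted(imps.items()):
            for st in studies:
                for k, (y, combo, x) in enumerate(st.patients):
                    row = {
                        "study_id": st.study_id,
                        "patient_id": k,
                        "arm_label": combo.canonical(cat),
                        "y": y,
                    }
                    for name, v in zip(dataset.covariate_names, np.atleast_1d(x)):
                        row[name] = v
                    if len(imps) > 1:
                        row["imputation"] = m
                    rows.append(row)
        paths["ipd"] = outdir / "ipd.csv"
        pd.DataFrame(rows).to_csv(paths["ipd"], index=False)
    if dataset.covariate_means is not None:
        paths["covariate_means"] = outdir / "covariate_means.csv"
        pd.DataFrame(
            {"covariate": dataset.covariate_names, "mean": dataset.covariate_means}
        ).to_csv(paths["covariate_means"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Network validation report
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Descriptive diagnostics of a component network (report only)."""

    combinations: list[str]
    component_usage: dict[str, int]
    subnetworks: list[set[str]]
    never_varies: list[str]

    @property
    def connected(self) -> bool:
        return len(self.subnetworks) <= 1

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "component": c,
                "n_combinations": self.component_usage[c],
                "never_varies_within_study": c in self.never_varies,
            }
            for c in self.component_usage
        ]
        return pd.DataFrame(rows)


def _study_arm_combos(dataset: NetworkDataset) -> list[list[TreatmentCombination]]:
    out = []
    for st in dataset.ad_contrast:
        out.append([a[0] for a in st.arms])
    for st in dataset.ad_arm:
        out.append([a[0] for a in st.arms])
    for st in dataset.ipd:
        out.append(st.combinations)
    return out


def validate_network(dataset: NetworkDataset) -> ValidationReport:
    """Describe the network: combinations, usage, connectivity, flat components.

    A component that is present in all arms, or absent from all arms, of
    every study that involves it can never vary within a study, so its main
    effect cancels from every contrast — a candidate for inestimability.
    Treatment-level disconnection is reported but is not an error: component
    models can bridge subnetworks through shared components.
    """
    cat = dataset.catalog
    per_study = _study_arm_combos(dataset)
    combos = dataset.all_combinations()
    usage = {
        c: sum(1 for combo in combos if c in combo.members) for c in cat.codes
    }
    g = nx.Graph()
    for arms in per_study:
        labels = [c.canonical(cat) for c in arms]
        g.add_nodes_from(labels)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                g.add_edge(labels[i], labels[j])
    subnets = [set(c) for c in nx.connected_components(g)]
    never_varies = []
    for code in cat.codes:
        varies = False
        used = False
        for arms in per_study:
            present = [code in c.members for c in arms]
            if any(present):
                used = True
            if any(present) and not all(present):
                varies = True
                break
        if used and not varies:
            never_varies.append(code)
    return ValidationReport(
        combinations=[c.canonical(cat) for c in combos],
        component_usage=usage,
        subnetworks=subnets,
        never_varies=never_varies,
    )
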