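"""Ground-truth data generators for exercising the full pipeline.

Real HCM-scale cohorts are not redistributable, so this module builds
statistically comparable stand-ins: Gaussian mixtures with known
parameters (for parameter-recovery oracles) and clinical-style tables of
648 patients by 20 continuous features with injected missingness,
displaced outlier rows, exact-copy columns and case-twin column names —
every artefact annotated so curation recall can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import RawTable

__all__ = [
    "GroundTruthMixture",
    "ClinicalTableSpec",
    "sample_mixture",
    "make_clinical_table",
    "random_mixture",
]

#: generic continuous clinical-style variable names; pairwise edit
#: distance >= 2 so only deliberately injected twins trip the
#: name-deduplication rule
_CLINICAL_NAMES = [
    "age", "bmi", "heart_rate", "sys_bp", "dia_bp",
    "lv_ef", "lv_mass", "la_diam", "ivs_thick", "pw_thick",
    "qrs_dur", "qtc_int", "gls_pct", "e_over_a", "crp_mgl",
    "hb_gdl", "egfr", "chol_tot", "trig", "nt_probnp",
]


def _feature_names(d: int) -> list[str]:
    names = list(_CLINICAL_NAMES[:d])
    # doubled index keeps pairwise edit distance >= 2 among coded names
    names += [f"var_{j:02d}{j:02d}" for j in range(len(names), d)]
    return names


@dataclass
class GroundTruthMixture:
    """A fully specified Gaussian mixture used as a sampling oracle."""

    weights: np.ndarray
    means: np.ndarray  # k x d
    covariances: np.ndarray  # k x d x d SPD
    n: int
    seed: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        for cov in self.covariances:
            np.linalg.cholesky(cov)  # SPD check

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def d(self) -> int:
        return self.means.shape[1]


def sample_mixture(truth: GroundTruthMixture) -> tuple[np.ndarray, np.ndarray]:
    """Draw truth.n points; returns (matrix, true component labels).

    Component counts are multinomial in the weights; rows are shuffled so
    labels are not blocked.  Byte-identical per seed.
    """
    rng = np.random.default_rng(truth.seed)
    counts = rng.multinomial(truth.n, truth.weights)
    parts, labels = [], []
    for c in range(truth.k):
        if counts[c] == 0:
            continue
        chol = np.linalg.cholesky(truth.covariances[c])
        z = rng.standard_normal((counts[c], truth.d))
        parts.append(truth.means[c] + z @ chol.T)
        labels.append(np.full(counts[c], c))
    if parts:
        X = np.concatenate(parts)
        y = np.concatenate(labels)
    else:
        X = np.empty((0, truth.d))
        y = np.empty(0, dtype=int)
    perm = rng.permutation(len(X))
    return X[perm], y[perm]


def random_mixture(
    k: int,
    d: int,
    n: int,
    seed: int,
    separation: float = 10.0,
    mean_offset: float = 0.0,
) -> GroundTruthMixture:
    """A random well-conditioned mixture: unit-scale within-component SD
    and component means ``separation`` SDs apart on average."""
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.full(k, 5.0))
    means = mean_offset + rng.standard_normal((k, d)) * separation / np.sqrt(2.0)
    covs = np.empty((k, d, d))
    for c in range(k):
        A = rng.standard_normal((d, d)) / np.sqrt(d)
        covs[c] = A @ A.T + np.eye(d)
    return GroundTruthMixture(weights, means, covs, n=n, seed=seed + 1)


@dataclass
class ClinicalTableSpec:
    """Shape and contamination profile of an emulated clinical cohort.

    Defaults mirror the cohort scale the generator targets: 648 patients
    and 20 continuous features, organised in correlated blocks with 2-4
    modes each, plus a small dose of every artefact the curation stage
    must handle.
    """

    n_patients: int = 648
    n_features: int = 20
    missing_rate: float = 0.01  # sporadic MCAR, applied to every 4th feature
    n_high_missing: int = 1  # features pushed above the eligibility cutoff
    high_missing_rate: float = 0.40
    outlier_rate: float = 0.05
    outlier_shift_sds: tuple[float, float] = (8.0, 12.0)
    n_duplicate_features: int = 1
    n_name_twins: int = 1
    block_size: int = 4
    n_strata: int = 5  # latent patient subgroups shifting every block
    stratum_separation: float = 5.0  # mean shift between strata, in within-SDs
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.missing_rate, self.high_missing_rate, self.outlier_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class TableAnnotations:
    """Ground truth of every injected artefact, for curation recall."""

    outlier_rows: np.ndarray
    duplicate_columns: dict[str, str]  # copy name -> source name
    name_twin_columns: dict[str, str]
    high_missing_features: list[str]
    missing_cells: np.ndarray  # bool over the final table shape
    feature_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "outlier_rows": self.outlier_rows.tolist(),
            "duplicate_columns": self.duplicate_columns,
            "name_twin_columns": self.name_twin_columns,
            "high_missing_features": self.high_missing_features,
            "n_missing_cells": int(self.missing_cells.sum()),
            "feature_names": self.feature_names,
        }


def _base_cohort(spec: ClinicalTableSpec, rng: np.random.Generator) -> np.ndarray:
    """Latent patient strata over correlated feature blocks.

    Each patient belongs to one of ``n_strata`` subgroups (think disease
    severity classes); every block of features has a within-block
    correlation structure and a per-stratum mean shift.  Alternate blocks
    get near-zero shifts, so roughly half the features come out unimodal
    and half multimodal.  Features are finally mapped affinely into
    positive clinical-looking ranges so coefficients of variation are
    well defined.
    """
    n, d, G = spec.n_patients, spec.n_features, spec.n_strata
    strata = rng.choice(G, size=n, p=rng.dirichlet(np.full(G, 8.0)))
    X = np.empty((n, d))
    j = 0
    block_idx = 0
    while j < d:
        width = min(spec.block_size, d - j)
        A = rng.standard_normal((width, width)) / np.sqrt(width)
        cov = A @ A.T + np.eye(width)
        chol = np.linalg.cholesky(cov)
        sep = spec.stratum_separation if block_idx % 2 == 0 else 0.3
        centers = rng.standard_normal((G, width)) * sep / np.sqrt(2.0)
        z = rng.standard_normal((n, width)) @ chol.T
        block = centers[strata] + z
        scale = rng.uniform(0.5, 5.0, size=width)
        offset = rng.uniform(30.0, 120.0, size=width)
        X[:, j : j + width] = block * scale + offset
        j += width
        block_idx += 1
    return X


def make_clinical_table(
    spec: ClinicalTableSpec | None = None,
) -> tuple[RawTable, TableAnnotations]:
    """Emulated raw cohort with annotated artefacts.

    Construction order: base features, outlier rows displaced by 8-12
    feature-SDs, duplicate/twin columns appended, then missingness
    injected completely at random per feature.  Outlier rows are kept
    fully observed so the annotated outliers are exactly the rows an
    ideal complete-case detector could see.
    """
    spec = spec or ClinicalTableSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    X = _base_cohort(spec, rng)
    names = _feature_names(spec.n_features)

    n_out = int(np.ceil(spec.outlier_rate * n))
    outlier_rows = rng.choice(n, size=n_out, replace=False)
    lo, hi = spec.outlier_shift_sds
    sds = X.std(axis=0)
    for row in outlier_rows:
        shift = rng.uniform(lo, hi, size=spec.n_features) * sds
        signs = rng.choice([-1.0, 1.0], size=spec.n_features)
        X[row] = X[row] + signs * shift

    # duplicate/twin sources avoid the high-missingness features so the
    # injected artefacts are attributable to a single curation rule each
    src_lo = min(spec.n_high_missing, spec.n_features - 1)
    cols = [X[:, j] for j in range(spec.n_features)]
    duplicate_columns: dict[str, str] = {}
    for i in range(spec.n_duplicate_features):
        src = int(rng.integers(src_lo, spec.n_features))
        name = f"{names[src]}_copy" if i == 0 else f"{names[src]}_copy{i}"
        cols.append(X[:, src].copy())
        names.append(name)
        duplicate_columns[name] = names[src]

    name_twin_columns: dict[str, str] = {}
    for i in range(spec.n_name_twins):
        src = int(rng.integers(src_lo, spec.n_features))
        twin = names[src].capitalize() if i == 0 else names[src].upper()
        # independent values: only the name collides
        cols.append(rng.normal(X[:, src].mean(), max(sds[src], 1.0), size=n))
        names.append(twin)
        name_twin_columns[twin] = names[src]

    table = np.column_stack(cols)
    d_total = table.shape[1]
    missing = np.zeros((n, d_total), dtype=bool)
    high_missing = []
    non_outliers = np.setdiff1d(np.arange(n), outlier_rows)
    for j in range(spec.n_features):
        rate = spec.missing_rate if j % 4 == 2 else 0.0
        if j < spec.n_high_missing:
            rate = spec.high_missing_rate
            high_missing.append(names[j])
        if rate > 0:
            hit = non_outliers[rng.random(len(non_outliers)) < rate]
            missing[hit, j] = True
    values = table.copy()
    values[missing] = np.nan

    raw = RawTable(
        features=names, values=values, missing_mask=missing, non_numeric=frozenset()
    )
    ann = TableAnnotations(
        outlier_rows=np.sort(outlier_rows),
        duplicate_columns=duplicate_columns,
        name_twin_columns=name_twin_columns,
        high_missing_features=high_missing,
        missing_cells=missing,
        feature_names=names,
    )
    return raw, ann


def table_to_dataframe(raw: RawTable) -> pd.DataFrame:
    """Render a raw table as a DataFrame (NaN marks missing cells)."""
    return pd.DataFrame(raw.values, columns=raw.features)
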