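"""Synthetic-vs-real fidelity indicators.

Five indicators compare a virtual cohort against the real one: mean
absolute per-feature coefficient-of-variation difference, inter-feature
and intra-patient correlation differences, a goodness-of-fit score (mean
per-feature two-sample Kolmogorov-Smirnov statistic), and a mean
per-feature histogram Kullback-Leibler divergence.  All indicators are
non-negative, vanish when the two cohorts coincide (KL up to its
smoothing floor), and shrink toward zero as same-distribution cohorts
grow.  Kernel-density overlays are provided for visual inspection of
the per-feature marginals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, ks_2samp

logger = logging.getLogger(__name__)

__all__ = [
    "QualityReport",
    "cv_difference",
    "inter_correlation_difference",
    "intra_correlation_difference",
    "goodness_of_fit",
    "kl_divergence",
    "kde_overlay",
    "quality_report",
]

SCHEMA_VERSION = "1.0"
_MEAN_EPS = 1e-12


def _check_same_d(real: np.ndarray, synth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    real = np.asarray(real, dtype=float)
    synth = np.asarray(synth, dtype=float)
    if real.ndim != 2 or synth.ndim != 2:
        raise ValueError("cohorts must be 2-d arrays")
    if real.shape[1] != synth.shape[1]:
        raise ValueError(
            f"feature-count mismatch: {real.shape[1]} vs {synth.shape[1]}"
        )
    return real, synth


def _cv(col: np.ndarray) -> float:
    return float(col.std(ddof=1) / abs(col.mean()))


def cv_difference(
    real: np.ndarray, synth: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean absolute difference of per-feature coefficients of variation.

    cV = sample SD / |mean|; features whose mean is numerically zero in
    either cohort are skipped (NaN in the per-feature vector) since cV is
    undefined there.
    """
    real, synth = _check_same_d(real, synth)
    d = real.shape[1]
    per_feature = np.full(d, np.nan)
    for j in range(d):
        if abs(real[:, j].mean()) <= _MEAN_EPS or abs(synth[:, j].mean()) <= _MEAN_EPS:
            logger.warning("feature %d skipped in cV: mean numerically zero", j)
            continue
        per_feature[j] = abs(_cv(real[:, j]) - _cv(synth[:, j]))
    valid = ~np.isnan(per_feature)
    if not valid.any():
        raise ValueError("no feature with a usable coefficient of variation")
    return float(per_feature[valid].mean()), per_feature


def _corr_matrix(X: np.ndarray) -> np.ndarray:
    """Feature-feature Pearson correlations; constant features give 0."""
    sd = X.std(axis=0)
    const = sd == 0.0
    if const.any():
        logger.warning("%d constant feature(s) contribute correlation 0", const.sum())
    Xs = (X - X.mean(axis=0)) / np.where(const, 1.0, sd)
    C = (Xs.T @ Xs) / X.shape[0]
    C[const, :] = 0.0
    C[:, const] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def inter_correlation_difference(real: np.ndarray, synth: np.ndarray) -> float:
    """Mean absolute difference of the two feature-correlation matrices
    over strict upper-triangle entries."""
    real, synth = _check_same_d(real, synth)
    d = real.shape[1]
    if d < 2:
        raise ValueError("inter-correlation needs at least 2 features")
    iu = np.triu_indices(d, k=1)
    diff = np.abs(_corr_matrix(real)[iu] - _corr_matrix(synth)[iu])
    return float(diff.mean())


def _mean_abs_row_correlation(X: np.ndarray, chunk: int = 1024) -> float:
    """Mean absolute off-diagonal patient-patient Pearson correlation.

    Columns are standardised first, then rows are correlated over the d
    features.  Computed in row blocks so large cohorts never materialise
    the full n x n matrix.
    """
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows for intra-correlation")
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd == 0.0, 1.0, sd)
    # row-centre and row-normalise: correlation between rows over features
    Z = Z - Z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    Z = Z / norms
    total = 0.0
    for start in range(0, n, chunk):
        block = Z[start : start + chunk]
        C = block @ Z.T
        rows = np.arange(start, start + block.shape[0])
        C[np.arange(block.shape[0]), rows] = 0.0  # drop self-correlations
        total += np.abs(C).sum()
    return float(total / (n * (n - 1)))


def intra_correlation_difference(real: np.ndarray, synth: np.ndarray) -> float:
    """Absolute difference of the cohorts' patient-patient correlation
    summaries (mean absolute off-diagonal row correlation), which makes
    cohorts of different sizes comparable."""
    real, synth = _check_same_d(real, synth)
    if real.shape[1] < 2:
        raise ValueError("intra-correlation needs at least 2 features")
    return abs(_mean_abs_row_correlation(real) - _mean_abs_row_correlation(synth))


def goodness_of_fit(
    real: np.ndarray, synth: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-feature two-sample Kolmogorov-Smirnov statistic in [0, 1]."""
    real, synth = _check_same_d(real, synth)
    if real.shape[0] == 0 or synth.shape[0] == 0:
        raise ValueError("cannot score an empty cohort")
    stats = np.array(
        [ks_2samp(real[:, j], synth[:, j]).statistic for j in range(real.shape[1])]
    )
    return float(stats.mean()), stats


def kl_divergence(
    real: np.ndarray, synth: np.ndarray, bins: int = 50
) -> tuple[float, np.ndarray]:
    """Mean per-feature histogram KL(real || synth) in nats.

    Both cohorts are binned on shared equal-width bins spanning the union
    range; probabilities use add-one (Laplace) smoothing so the estimate
    is finite.  Constant-in-both features contribute 0.  Asymmetric by
    construction: the real cohort is the reference.
    """
    real, synth = _check_same_d(real, synth)
    if bins < 2:
        raise ValueError("need at least 2 bins")
    d = real.shape[1]
    per_feature = np.zeros(d)
    for j in range(d):
        lo = min(real[:, j].min(), synth[:, j].min())
        hi = max(real[:, j].max(), synth[:, j].max())
        if hi == lo:
            logger.warning("feature %d constant in both cohorts; KL set to 0", j)
            continue
        edges = np.linspace(lo, hi, bins + 1)
        p_counts, _ = np.histogram(real[:, j], bins=edges)
        q_counts, _ = np.histogram(synth[:, j], bins=edges)
        p = (p_counts + 1.0) / (p_counts.sum() + bins)
        q = (q_counts + 1.0) / (q_counts.sum() + bins)
        per_feature[j] = float(np.sum(p * np.log(p / q)))
    return float(per_feature.mean()), per_feature


def kde_overlay(
    real: np.ndarray,
    synth: np.ndarray,
    feature: int,
    grid_size: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-kernel density curves of one feature on a shared grid.

    Silverman bandwidth per cohort; the grid spans the union range padded
    by 3 bandwidth-scaled SDs so each curve integrates to ~1.  Constant
    features are rendered as a narrow Gaussian spike at the constant.
    """
    real, synth = _check_same_d(real, synth)
    x_r, x_s = real[:, feature], synth[:, feature]

    def density(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
        if x.std() == 0.0:
            logger.warning("constant feature in KDE; rendering narrow spike")
            sigma = max(1e-3, 1e-3 * abs(x[0]))
            return np.exp(-0.5 * ((grid - x[0]) / sigma) ** 2) / (
                sigma * np.sqrt(2 * np.pi)
            )
        return gaussian_kde(x, bw_method="silverman")(grid)

    spread = max(x_r.std(), x_s.std(), 1e-3)
    lo = min(x_r.min(), x_s.min()) - 3 * spread
    hi = max(x_r.max(), x_s.max()) + 3 * spread
    grid = np.linspace(lo, hi, grid_size)
    return grid, density(x_r, grid), density(x_s, grid)


@dataclass
class QualityReport:
    """The five fidelity indicators plus per-feature breakdowns."""

    cv_diff: float
    inter_corr_diff: float
    intra_corr_diff: float
    gof: float
    kl: float
    per_feature: pd.DataFrame = field(repr=False)
    n_real: int = 0
    n_synth: int = 0

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "indicators": {
                "cv_diff": self.cv_diff,
                "inter_corr_diff": self.inter_corr_diff,
                "intra_corr_diff": self.intra_corr_diff,
                "gof": self.gof,
                "kl": self.kl,
            },
            "n_real": self.n_real,
            "n_synth": self.n_synth,
            "per_feature": self.per_feature.to_dict(orient="records"),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def quality_report(
    real: np.ndarray,
    synth: np.ndarray,
    feature_names: list[str] | None = None,
    bins: int = 50,
) -> QualityReport:
    """Compute all five indicators and the per-feature table at once."""
    real, synth = _check_same_d(real, synth)
    d = real.shape[1]
    names = feature_names if feature_names is not None else [f"f{j}" for j in range(d)]
    cv, cv_per = cv_difference(real, synth)
    inter = inter_correlation_difference(real, synth)
    intra = intra_correlation_difference(real, synth)
    gof, ks_per = goodness_of_fit(real, synth)
    kl, kl_per = kl_divergence(real, synth, bins=bins)
    per_feature = pd.DataFrame(
        {
            "feature": names,
            "cv_real": [
                _cv(real[:, j]) if abs(real[:, j].mean()) > _MEAN_EPS else np.nan
                for j in range(d)
            ],
            "cv_synth": [
                _cv(synth[:, j]) if abs(synth[:, j].mean()) > _MEAN_EPS else np.nan
                for j in range(d)
            ],
            "ks": ks_per,
            "kl": kl_per,
        }
    )
    return QualityReport(
        cv_diff=cv,
        inter_corr_diff=inter,
        intra_corr_diff=intra,
        gof=gof,
        kl=kl,
        per_feature=per_feature,
        n_real=real.shape[0],
        n_synth=synth.shape[0],
    )
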