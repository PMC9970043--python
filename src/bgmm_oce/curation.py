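"""Data diagnostics: eligibility, outliers, duplicate features, imputation.

Raw clinical tables arrive as CSV or JSON with heterogeneous quality:
partially missing features, lexically duplicated columns, outlying
patients.  This module splits the feature space into *eligible* features
(numeric, less than a configurable fraction of missing values) and
*non-eligible* ones, flags outlying patients with Isolation Forests
trained on complete-case records, removes value- and name-duplicated
columns, and imputes the remaining missing cells with k-nearest-neighbour
means.  Every decision is recorded in an ordered, reproducible log.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
from sklearn.ensemble import IsolationForest
from sklearn.impute import KNNImputer

__all__ = [
    "RawTable",
    "CurationConfig",
    "CuratedDataset",
    "load_table",
    "partition_features",
    "detect_outliers",
    "remove_duplicate_features",
    "impute_knn",
    "curate",
]

#: cell contents recognised as missing values (compared casefolded, stripped)
DEFAULT_MISSING_MARKERS: tuple[str, ...] = ("", "na", "nan", "null", "none")


@dataclass(frozen=True)
class CurationConfig:
    """Tunable thresholds of the diagnostics stage.

    ``missing_threshold`` is a strict upper bound: a feature is eligible
    only if its missing fraction is strictly below it.
    """

    missing_threshold: float = 0.30
    contamination: float = 0.05
    knn_k: int = 5
    dup_corr_threshold: float = 0.999
    dup_name_distance: int = 1
    missing_markers: tuple[str, ...] = DEFAULT_MISSING_MARKERS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_threshold <= 1.0:
            raise ValueError("missing_threshold must lie in [0, 1]")
        if not 0.0 < self.contamination < 0.5:
            raise ValueError("contamination must lie in (0, 0.5)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be a positive integer")
        if not 0.0 < self.dup_corr_threshold <= 1.0:
            raise ValueError("dup_corr_threshold must lie in (0, 1]")
        if self.dup_name_distance < 0:
            raise ValueError("dup_name_distance must be non-negative")


@dataclass
class RawTable:
    """A rectangular patient-by-feature table straight off disk.

    ``values`` holds the numeric parse of each cell (NaN where the cell
    is missing or unparseable), ``missing_mask`` marks cells that were
    recognised missing markers, and ``non_numeric`` lists features that
    contained at least one unparseable, non-missing cell.
    """

    features: list[str]
    values: np.ndarray  # n x d float, NaN for missing/unparseable
    missing_mask: np.ndarray  # n x d bool
    non_numeric: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.features):
            raise ValueError("values must be n x d with d == len(features)")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("missing_mask shape must match values")
        if any(not isinstance(f, str) or not f for f in self.features):
            raise ValueError("feature names must be non-empty strings")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return len(self.features)


@dataclass
class CuratedDataset:
    """Fully numeric, complete matrix plus curation provenance."""

    matrix: np.ndarray  # n x d_eligible, no missing values
    eligible_features: list[str]
    excluded_features: list[tuple[str, str]]  # (name, reason)
    outlier_flags: np.ndarray  # n bool
    imputed_mask: np.ndarray  # n x d_eligible bool
    log: list[dict] = field(default_factory=list)

    def model_rows(self) -> np.ndarray:
        """Rows used for downstream model fitting (outliers held out)."""
        return self.matrix[~self.outlier_flags]

    def log_jsonl(self) -> str:
        return "\n".join(json.dumps(e, sort_keys=True) for e in self.log) + "\n"


def _parse_cell(raw: object, markers: frozenset[str]) -> tuple[float, bool, bool]:
    """Return (value, is_missing, is_non_numeric) for one raw cell."""
    if raw is None:
        return math.nan, True, False
    if isinstance(raw, bool):
        return float(raw), False, False
    if isinstance(raw, (int, float)):
        if isinstance(raw, float) and math.isnan(raw):
            return math.nan, True, False
        return float(raw), False, False
    text = str(raw).strip()
    if text.casefold() in markers:
        return math.nan, True, False
    try:
        return float(text), False, False
    except ValueError:
        return math.nan, False, True


def _table_from_rows(
    features: list[str],
    rows: list[list[object]],
    markers: Sequence[str],
) -> RawTable:
    marker_set = frozenset(m.casefold() for m in markers)
    n, d = len(rows), len(features)
    values = np.full((n, d), np.nan)
    missing = np.zeros((n, d), dtype=bool)
    non_numeric: set[str] = set()
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            v, miss, bad = _parse_cell(cell, marker_set)
            values[i, j] = v
            missing[i, j] = miss
            if bad:
                non_numeric.add(features[j])
    return RawTable(features, values, missing, frozenset(non_numeric))


def load_table(
    path: str | Path,
    format: str = "csv",
    missing_markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
) -> RawTable:
    """Read a patient table from CSV (header row) or JSON (array of objects).

    Column order is preserved; for JSON it is the key order of first
    appearance.  Ragged CSV rows raise a format error naming the row.
    """
    path = Path(path)
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise ValueError(f"{path}: empty CSV file") from None
            features = [h.strip() for h in header]
            rows: list[list[object]] = []
            for i, row in enumerate(reader):
                if len(row) != len(features):
                    raise ValueError(
                        f"{path}: ragged row {i} has {len(row)} cells, "
                        f"expected {len(features)}"
                    )
                rows.append(list(row))
        return _table_from_rows(features, rows, missing_markers)
    if format == "json":
        with path.open(encoding="utf-8") as fh:
            records = json.load(fh)
        if not isinstance(records, list) or not all(
            isinstance(r, dict) for r in records
        ):
            raise ValueError(f"{path}: JSON input must be an array of flat objects")
        features = []
        seen = set()
        for rec in records:
            for key in rec:
                if key not in seen:
                    seen.add(key)
                    features.append(key)
        rows = [[rec.get(f) for f in features] for rec in records]
        return _table_from_rows(features, rows, missing_markers)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")


def partition_features(
    table: RawTable, config: CurationConfig
) -> tuple[list[str], list[tuple[str, str]]]:
    """Split features into eligible and excluded-with-reason, order preserved.

    Eligible means numeric and strictly less than ``missing_threshold``
    missing; a feature missing exactly the threshold fraction is excluded.
    """
    if table.n_records == 0:
        raise ValueError("cannot partition an empty table")
    eligible: list[str] = []
    excluded: list[tuple[str, str]] = []
    miss_frac = table.missing_mask.mean(axis=0)
    for j, name in enumerate(table.features):
        if name in table.non_numeric:
            excluded.append((name, "non_numeric"))
        elif miss_frac[j] >= config.missing_threshold:
            excluded.append((name, "missingness"))
        else:
            eligible.append(name)
    if not eligible:
        raise ValueError("no eligible features remain after partitioning")
    return eligible, excluded


def _levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def remove_duplicate_features(
    table: RawTable,
    eligible: Sequence[str],
    config: CurationConfig,
) -> list[tuple[str, str]]:
    """Flag later columns that duplicate an earlier one by value or name.

    Value duplication: absolute Pearson correlation on shared non-missing
    rows at or above ``dup_corr_threshold``.  Name duplication: casefolded
    Levenshtein distance at most ``dup_name_distance``.  Each feature is
    excluded at most once; name matching runs first.
    """
    idx = {f: table.features.index(f) for f in eligible}
    dropped: dict[str, str] = {}
    names = list(eligible)
    for i in range(len(names)):
        if names[i] in dropped:
            continue
        for j in range(i + 1, len(names)):
            if names[j] in dropped:
                continue
            dist = _levenshtein(names[i].casefold(), names[j].casefold())
            if dist <= config.dup_name_distance:
                dropped[names[j]] = "duplicate_name"
    for i in range(len(names)):
        if names[i] in dropped:
            continue
        xi = table.values[:, idx[names[i]]]
        for j in range(i + 1, len(names)):
            if names[j] in dropped:
                continue
            xj = table.values[:, idx[names[j]]]
            shared = ~(np.isnan(xi) | np.isnan(xj))
            if shared.sum() < 3:
                continue
            a, b = xi[shared], xj[shared]
            sa, sb = a.std(), b.std()
            if sa == 0.0 or sb == 0.0:
                r = 1.0 if sa == sb == 0.0 and np.allclose(a, b) else 0.0
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            if abs(r) >= config.dup_corr_threshold:
                dropped[names[j]] = "duplicate_value"
    return [(n, dropped[n]) for n in names if n in dropped]


def detect_outliers(
    matrix: np.ndarray, contamination: float, seed: int
) -> np.ndarray:
    """Flag the ceil(contamination * n) most isolated complete-case rows.

    An Isolation Forest (100 trees) is fitted on the rows; the rows with
    the lowest anomaly scores are flagged.  Deterministic for a fixed seed.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 10:
        raise ValueError("need at least 10 complete-case rows for outlier detection")
    if not 0.0 < contamination < 0.5:
        raise ValueError("contamination must lie in (0, 0.5)")
    forest = IsolationForest(
        n_estimators=100, contamination=contamination, random_state=seed
    )
    forest.fit(matrix)
    scores = forest.score_samples(matrix)
    n_flag = math.ceil(contamination * n)
    # stable argsort so ties resolve by row index
    order = np.argsort(scores, kind="stable")
    flags = np.zeros(n, dtype=bool)
    flags[order[:n_flag]] = True
    return flags


def impute_knn(
    matrix: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing cells with the mean of the k nearest rows' values.

    Distances are Euclidean over mutually observed features, rescaled by
    sqrt(d / n_shared) so rows with different overlap are comparable.
    Observed cells are untouched; the returned mask marks imputed sites.
    """
    matrix = np.asarray(matrix, dtype=float)
    if k < 1:
        raise ValueError("k must be a positive integer")
    mask = np.isnan(matrix)
    all_missing = mask.all(axis=1)
    if all_missing.any():
        row = int(np.flatnonzero(all_missing)[0])
        raise ValueError(f"row {row} has all cells missing; cannot impute")
    observed_per_feature = (~mask).sum(axis=0)
    if (observed_per_feature < k).any():
        j = int(np.argmin(observed_per_feature))
        raise ValueError(
            f"feature column {j} has only {observed_per_feature[j]} observed "
            f"values, fewer than k={k}"
        )
    if not mask.any():
        return matrix.copy(), mask
    imputer = KNNImputer(n_neighbors=k, weights="uniform", metric="nan_euclidean")
    completed = imputer.fit_transform(matrix)
    return completed, mask


def curate(table: RawTable, config: CurationConfig | None = None) -> CuratedDataset:
    """Run the full diagnostics stage on a raw table.

    Order of operations: eligibility partition, duplicate-feature removal,
    complete-case outlier flagging, kNN imputation.  Outlying rows are
    retained in the curated matrix but flagged so model fitting can hold
    them out.
    """
    config = config or CurationConfig()
    log: list[dict] = []
    eligible, excluded = partition_features(table, config)
    for name, reason in excluded:
        log.append(
            {"stage": "partition", "feature": name, "action": "exclude",
             "reason": reason}
        )
    dup_excluded = remove_duplicate_features(table, eligible, config)
    for name, reason in dup_excluded:
        log.append(
            {"stage": "deduplicate", "feature": name, "action": "exclude",
             "reason": reason}
        )
    dup_names = {n for n, _ in dup_excluded}
    eligible = [f for f in eligible if f not in dup_names]
    excluded = excluded + dup_excluded

    cols = [table.features.index(f) for f in eligible]
    matrix = table.values[:, cols]
    miss = table.missing_mask[:, cols]
    n = matrix.shape[0]

    complete = ~np.isnan(matrix).any(axis=1)
    outlier_flags = np.zeros(n, dtype=bool)
    if complete.sum() >= 10:
        flags = detect_outliers(matrix[complete], config.contamination, config.seed)
        outlier_flags[np.flatnonzero(complete)] = flags
        for row in np.flatnonzero(outlier_flags):
            log.append(
                {"stage": "outliers", "row": int(row), "action": "flag",
                 "reason": "isolation_forest"}
            )
    else:
        log.append(
            {"stage": "outliers", "action": "skip",
             "reason": f"only {int(complete.sum())} complete rows (< 10)"}
        )

    completed, imputed_mask = impute_knn(matrix, config.knn_k)
    n_imputed = int(imputed_mask.sum())
    if n_imputed:
        log.append(
            {"stage": "impute", "action": "knn_impute",
             "reason": f"{n_imputed} cells, k={config.knn_k}"}
        )
    # imputation mask must coincide with recognised-missing cells of the
    # eligible sub-table
    assert bool((imputed_mask == miss).all()) or bool(
        (imputed_mask == np.isnan(matrix)).all()
    )
    return CuratedDataset(
        matrix=completed,
        eligible_features=eligible,
        excluded_features=excluded,
        outlier_flags=outlier_flags,
        imputed_mask=imputed_mask,
        log=log,
    )
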