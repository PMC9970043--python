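"""Diagnostics stage: eligibility, duplicates, outliers, imputation."""

import json

import numpy as np
import pytest

import bgmm_oce as bo
from bgmm_oce.curation import (
    CurationConfig,
    RawTable,
    curate,
    detect_outliers,
    impute_knn,
    load_table,
    partition_features,
    remove_duplicate_features,
)


def _table(values, features=None, missing=None):
    values = np.asarray(values, dtype=float)
    if features is None:
        features = [f"c{j}" for j in range(values.shape[1])]
    if missing is None:
        missing = np.isnan(values)
    return RawTable(features=features, values=values, missing_mask=missing)


class TestLoadTable:
    def test_csv_round_trip(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("age,bmi\n50,22.5\n61,NA\n47,30\n")
        t = load_table(p, "csv")
        assert t.features == ["age", "bmi"]
        assert t.n_records == 3
        assert t.missing_mask[1, 1] and not t.missing_mask[0, 0]
        assert t.values[0, 1] == 22.5

    def test_json_records(self, tmp_path):
        p = tmp_path / "t.json"
        p.write_text(json.dumps([{"a": 1, "b": 2}] * 3))
        t = load_table(p, "json")
        assert t.n_records == 3 and t.features == ["a", "b"]

    def test_json_missing_key_is_missing(self, tmp_path):
        p = tmp_path / "t.json"
        p.write_text(json.dumps([{"a": 1, "b": 2}, {"a": 3}]))
        t = load_table(p, "json")
        assert t.missing_mask[1, 1]

    def test_ragged_row_names_index(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n3\n")
        with pytest.raises(ValueError, match="row 1"):
            load_table(p, "csv")

    def test_non_numeric_cells_tag_feature(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,b\n1,male\n2,female\n")
        t = load_table(p, "csv")
        assert t.non_numeric == {"b"}


class TestPartition:
    def test_heavy_missingness_excluded(self):
        vals = np.ones((10, 2))
        vals[:4, 1] = np.nan  # 40% missing
        eligible, excluded = partition_features(_table(vals), CurationConfig())
        assert eligible == ["c0"]
        assert ("c1", "missingness") in excluded

    def test_boundary_is_strict(self):
        vals = np.ones((10, 2))
        vals[:3, 1] = np.nan  # exactly 30%: not < 0.30
        _, excluded = partition_features(_table(vals), CurationConfig())
        assert ("c1", "missingness") in excluded

    def test_complete_table_all_eligible(self):
        eligible, excluded = partition_features(
            _table(np.ones((5, 3))), CurationConfig()
        )
        assert len(eligible) == 3 and excluded == []

    def test_all_excluded_errors(self):
        vals = np.full((10, 1), np.nan)
        vals[:2, 0] = 1.0  # 80% missing
        with pytest.raises(ValueError, match="no eligible"):
            partition_features(_table(vals), CurationConfig())

    @pytest.mark.parametrize("thresholds", [(0.1, 0.3), (0.3, 0.5), (0.05, 0.95)])
    def test_raising_threshold_never_shrinks_eligible(self, thresholds):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((40, 6))
        vals[rng.random((40, 6)) < 0.25] = np.nan
        lo, hi = thresholds

        def eligible_at(th):
            try:
                e, _ = partition_features(
                    _table(vals), CurationConfig(missing_threshold=th)
                )
                return set(e)
            except ValueError:  # everything excluded at this threshold
                return set()

        assert eligible_at(lo) <= eligible_at(hi)

    def test_partition_completeness(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((20, 5))
        vals[rng.random((20, 5)) < 0.4] = np.nan
        try:
            eligible, excluded = partition_features(_table(vals), CurationConfig())
        except ValueError:
            return
        names = eligible + [n for n, _ in excluded]
        assert sorted(names) == [f"c{j}" for j in range(5)]


class TestOutliers:
    def test_distant_point_flagged(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 3)) * 0.1
        X[57] = [100.0, 100.0, 100.0]
        flags = detect_outliers(X, contamination=0.05, seed=0)
        assert flags[57]

    def test_exact_flag_count(self):
        rng = np.random.default_rng(1)
        flags = detect_outliers(rng.standard_normal((200, 2)), 0.05, seed=0)
        assert flags.sum() == 10

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 2))
        assert np.array_equal(
            detect_outliers(X, 0.1, seed=3), detect_outliers(X, 0.1, seed=3)
        )

    def test_identical_rows_no_crash(self):
        flags = detect_outliers(np.ones((200, 2)), 0.05, seed=0)
        assert flags.shape == (200,)

    def test_too_few_rows_errors(self):
        with pytest.raises(ValueError, match="at least 10"):
            detect_outliers(np.ones((5, 2)), 0.05, seed=0)


class TestDuplicates:
    def test_identical_values_excluded(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        t = _table(np.column_stack([x, x]), features=["x", "x_copy"])
        out = remove_duplicate_features(t, ["x", "x_copy"], CurationConfig())
        assert out == [("x_copy", "duplicate_value")]

    def test_case_twin_names_excluded(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((50, 2))
        t = _table(vals, features=["Age", "age"])
        out = remove_duplicate_features(t, ["Age", "age"], CurationConfig())
        assert out == [("age", "duplicate_name")]

    def test_independent_columns_kept(self):
        rng = np.random.default_rng(2)
        t = _table(rng.standard_normal((500, 2)), features=["alpha", "bravo"])
        assert remove_duplicate_features(t, ["alpha", "bravo"], CurationConfig()) == []


class TestImpute:
    def test_complete_matrix_is_identity(self):
        X = np.arange(12.0).reshape(4, 3)
        out, mask = impute_knn(X, k=2)
        assert np.array_equal(out, X) and not mask.any()

    def test_twin_row_fills_value(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [50.0, 60.0, 70.0]])
        out, mask = impute_knn(X, k=1)
        assert out[1, 2] == 3.0 and mask[1, 2]

    def test_two_neighbor_mean(self):
        # nearest two rows to row 0 carry 4 and 6 in the missing feature
        X = np.array(
            [
                [0.0, 0.0, np.nan],
                [0.0, 0.1, 4.0],
                [0.0, -0.1, 6.0],
                [100.0, 100.0, 50.0],
            ]
        )
        out, _ = impute_knn(X, k=2)
        assert out[0, 2] == pytest.approx(5.0)

    def test_all_missing_row_errors(self):
        X = np.array([[1.0, 2.0], [np.nan, np.nan], [3.0, 4.0]])
        with pytest.raises(ValueError, match="row 1"):
            impute_knn(X, k=1)


class TestCurate:
    def test_fixture_cohort_fully_curated(self, cohort_csv):
        _, raw, ann = cohort_csv
        cur = curate(raw, CurationConfig(seed=0))
        assert not np.isnan(cur.matrix).any()
        reasons = dict(cur.excluded_features)
        for copy_name in ann.duplicate_columns:
            assert reasons[copy_name] == "duplicate_value"
        for twin_name in ann.name_twin_columns:
            assert reasons[twin_name] == "duplicate_name"
        for feat in ann.high_missing_features:
            assert reasons[feat] == "missingness"
        # eligible + excluded partition the raw feature set
        names = cur.eligible_features + [n for n, _ in cur.excluded_features]
        assert sorted(names) == sorted(raw.features)
        # imputation happened exactly at missing cells of eligible columns
        cols = [raw.features.index(f) for f in cur.eligible_features]
        assert np.array_equal(cur.imputed_mask, raw.missing_mask[:, cols])

    def test_log_is_deterministic(self, cohort_csv):
        _, raw, _ = cohort_csv
        log1 = curate(raw, CurationConfig(seed=5)).log_jsonl()
        log2 = curate(raw, CurationConfig(seed=5)).log_jsonl()
        assert log1 == log2
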