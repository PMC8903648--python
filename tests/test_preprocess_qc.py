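"""Preprocessing chain and QC replicate metrics."""

import numpy as np
import pandas as pd
import pytest

from phenolink.core_data import ExpressionMatrix
from phenolink.preprocess_qc import (
    PreprocessConfig,
    filter_noise_features,
    impute,
    log2_transform,
    median_normalize,
    qc_replicate_report,
)


def matrix(rows, samples=None, features=None, log2=True):
    rows = np.asarray(rows, dtype=float)
    samples = samples or [f"S{i}" for i in range(rows.shape[0])]
    features = features or [f"F{j}" for j in range(rows.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(rows, index=samples, columns=features), log2_transformed=log2
    )


class TestLog2:
    def test_closed_form_values(self):
        m = matrix([[8.0, 1.0]], log2=False)
        out = log2_transform(m)
        assert out.data.iloc[0].tolist() == [3.0, 0.0]
        assert out.log2_transformed

    def test_missing_stays_missing(self):
        out = log2_transform(matrix([[4.0, np.nan]], log2=False))
        assert np.isnan(out.data.iloc[0, 1])

    def test_non_positive_value_is_located(self):
        with pytest.raises(ValueError, match="S0.*F1"):
            log2_transform(matrix([[2.0, -1.0]], log2=False))

    def test_double_transform_rejected(self):
        with pytest.raises(ValueError, match="already"):
            log2_transform(matrix([[1.0]], log2=True))


class TestMedianNormalize:
    def test_odd_count_closed_form(self):
        out = median_normalize(matrix([[1.0, 2.0, 3.0]]), target=0.0)
        assert out.data.iloc[0].tolist() == [-1.0, 0.0, 1.0]

    def test_even_count_uses_mid_mean_median(self):
        out = median_normalize(matrix([[1.0, 2.0, 3.0, 4.0]]), target=0.0)
        assert out.data.iloc[0].tolist() == [-1.5, -0.5, 0.5, 1.5]

    def test_already_centered_sample_unchanged(self):
        m = matrix([[-1.0, 0.0, 1.0]])
        out = median_normalize(m, target=0.0)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_idempotent_and_exact(self):
        rng = np.random.default_rng(3)
        m = matrix(rng.normal(20, 2, size=(5, 11)))
        once = median_normalize(m, target=0.0)
        twice = median_normalize(once, target=0.0)
        assert np.allclose(once.data.median(axis=1), 0.0, atol=1e-9)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_nonzero_target_and_missing(self):
        m = matrix([[1.0, np.nan, 3.0]])
        out = median_normalize(m, target=5.0)
        assert np.nanmedian(out.data.iloc[0]) == 5.0
        assert np.isnan(out.data.iloc[0, 1])

    def test_all_missing_sample_is_named(self):
        with pytest.raises(ValueError, match="S0"):
            median_normalize(matrix([[np.nan, np.nan]]))


class TestNoiseFilter:
    def test_majority_missing_feature_removed(self):
        rows = np.full((6, 1), np.nan)
        rows[:2, 0] = 1.0  # present in 2 of 6 < 50%
        _, removed = filter_noise_features(matrix(rows), 0.5)
        assert removed == ["F0"]

    def test_boundary_is_inclusive(self):
        rows = np.full((6, 1), np.nan)
        rows[:3, 0] = 1.0  # exactly 50%
        kept, removed = filter_noise_features(matrix(rows), 0.5)
        assert removed == []
        assert kept.feature_ids == ["F0"]

    def test_zero_threshold_removes_nothing(self):
        rows = np.full((4, 3), np.nan)
        _, removed = filter_noise_features(matrix(rows), 0.0)
        assert removed == []

    def test_partition_is_exact(self):
        rng = np.random.default_rng(0)
        rows = rng.normal(size=(10, 30))
        rows[rng.random(rows.shape) < 0.5] = np.nan
        m = matrix(rows)
        kept, removed = filter_noise_features(m, 0.5)
        assert sorted(kept.feature_ids + removed) == sorted(m.feature_ids)
        fractions = kept.data.notna().mean(axis=0)
        assert (fractions >= 0.5).all()


class TestImpute:
    def test_global_min(self):
        out = impute(matrix([[1.0, np.nan], [3.0, 4.0]]), "global_min", 1.0)
        assert out.data.iloc[0, 1] == 1.0

    def test_feature_min_is_column_wise(self):
        out = impute(matrix([[1.0, np.nan], [3.0, 4.0]]), "feature_min", 1.0)
        assert out.data.iloc[0, 1] == 4.0

    def test_sample_min_is_row_wise(self):
        out = impute(matrix([[1.0, np.nan], [3.0, 4.0]]), "sample_min", 1.0)
        assert out.data.iloc[0, 1] == 1.0

    def test_scale_applied(self):
        out = impute(matrix([[2.0, np.nan]]), "global_min", 0.5)
        assert out.data.iloc[0, 1] == 1.0

    def test_complete_matrix_identity_for_every_method(self):
        m = matrix([[1.0, 2.0], [3.0, 4.0]])
        for method in ("global_min", "sample_min", "feature_min", "none"):
            pd.testing.assert_frame_equal(impute(m, method).data, m.data)

    def test_present_values_untouched_and_no_missing_left(self):
        rng = np.random.default_rng(1)
        rows = rng.normal(20, 3, size=(8, 15))
        mask = rng.random(rows.shape) < 0.2
        rows[mask] = np.nan
        m = matrix(rows)
        out = impute(m, "global_min", 0.9)
        assert not out.data.isna().any().any()
        present = ~m.data.isna()
        pd.testing.assert_frame_equal(out.data[present], m.data[present])
        assert out.data.min().min() == pytest.approx(0.9 * m.data.min().min())

    def test_all_missing_feature_is_hard_error(self):
        with pytest.raises(ValueError, match="F1"):
            impute(matrix([[1.0, np.nan], [2.0, np.nan]]), "feature_min")

    def test_all_missing_sample_is_hard_error(self):
        with pytest.raises(ValueError, match="S0"):
            impute(matrix([[np.nan, np.nan], [1.0, 2.0]]), "sample_min")


class TestQCReport:
    def test_identical_replicates_correlate_perfectly(self):
        rows = np.tile(np.arange(5.0), (2, 1))
        report = qc_replicate_report(matrix(rows), ["S0", "S1"])
        assert report.pairwise_correlations.loc["S0", "S1"] == pytest.approx(1.0)
        assert report.mean_correlation == pytest.approx(1.0)

    def test_reversed_ordering_gives_minus_one(self):
        rows = [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]
        report = qc_replicate_report(matrix(rows), ["S0", "S1"])
        assert report.mean_correlation == pytest.approx(-1.0)

    def test_cv_on_linear_scale(self):
        # linear values {1, 2, 3} across 3 QC samples: sd1 = 1, mean = 2
        rows = np.log2([[1.0], [2.0], [3.0]])
        report = qc_replicate_report(matrix(rows), ["S0", "S1", "S2"])
        assert report.per_feature_cv["F0"] == pytest.approx(0.5)
        assert report.median_cv == pytest.approx(0.5)

    def test_grid_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(2)
        rows = rng.normal(size=(4, 20))
        report = qc_replicate_report(matrix(rows), ["S0", "S1", "S2", "S3"])
        grid = report.pairwise_correlations.to_numpy()
        assert np.allclose(grid, grid.T)
        assert np.allclose(np.diag(grid), 1.0)
        assert np.nanmax(np.abs(grid)) <= 1.0 + 1e-12

    def test_sparse_pair_excluded_from_mean(self):
        rows = np.array([
            [1.0, 2.0, 3.0, np.nan, np.nan, np.nan],
            [np.nan, np.nan, np.nan, 1.0, 2.0, 4.0],
            [1.0, 2.0, 3.0, 1.0, 2.0, 4.0],
        ])
        report = qc_replicate_report(matrix(rows), ["S0", "S1", "S2"])
        assert np.isnan(report.pairwise_correlations.loc["S0", "S1"])
        assert np.isfinite(report.mean_correlation)

    def test_unknown_sample_is_hard_error(self):
        with pytest.raises(ValueError, match="nope"):
            qc_replicate_report(matrix([[1.0], [2.0]]), ["S0", "nope"])


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(min_observed_fraction=1.5)
    with pytest.raises(ValueError):
        PreprocessConfig(imputation_scale=0.0)
    with pytest.raises(ValueError):
        PreprocessConfig(imputation_method="knn")
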