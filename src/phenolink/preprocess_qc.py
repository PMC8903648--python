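"""Preprocessing and replicate-based quality control.

Covers the standard proteomics preprocessing chain: log2 transform, per-sample
median normalization, noise filtration of sparsely observed features,
minimum-value imputation, and QC-replicate correlation / coefficient-of-
variation reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ExpressionMatrix

__all__ = [
    "PreprocessConfig",
    "QCReport",
    "log2_transform",
    "median_normalize",
    "filter_noise_features",
    "impute",
    "qc_replicate_report",
]

IMPUTATION_METHODS = ("global_min", "sample_min", "feature_min", "none")


@dataclass
class PreprocessConfig:
    """Knobs for the preprocessing chain.

    min_observed_fraction: keep a feature only if it is observed in at least
    this fraction of samples (default 0.5, i.e. the "expressed in less than
    50% of samples is noise" rule; the boundary is inclusive).
    imputation_scale multiplies the minimum used to fill missing values.
    """

    apply_log2: bool = False
    normalization_target: float = 0.0
    min_observed_fraction: float = 0.5
    imputation_method: str = "global_min"
    imputation_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_observed_fraction <= 1.0:
            raise ValueError("min_observed_fraction must be in [0, 1]")
        if self.imputation_scale <= 0:
            raise ValueError("imputation_scale must be > 0")
        if self.imputation_method not in IMPUTATION_METHODS:
            raise ValueError(
                f"imputation_method must be one of {IMPUTATION_METHODS}, "
                f"got {self.imputation_method!r}"
            )


@dataclass
class QCReport:
    """Replicate reproducibility summary over designated QC samples.

    pairwise_correlations is a symmetric sample x sample grid of Pearson r
    (unit diagonal, NaN where a pair shares < 3 observed features);
    per_feature_cv holds coefficients of variation computed across the QC
    samples on the linear intensity scale.
    """

    qc_sample_ids: list[str]
    pairwise_correlations: pd.DataFrame
    mean_correlation: float
    per_feature_cv: pd.Series
    median_cv: float
    correlation_method: str = "pearson"
    cv_scale: str = "linear"

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: pairwise r rows followed by per-feature CV rows."""
        rows = []
        ids = self.qc_sample_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                rows.append(
                    {"metric": "correlation", "item_a": a, "item_b": b,
                     "value": self.pairwise_correlations.loc[a, b]}
                )
        rows.append({"metric": "mean_correlation", "item_a": "", "item_b": "",
                     "value": self.mean_correlation})
        for feature, cv in self.per_feature_cv.items():
            rows.append({"metric": "cv", "item_a": feature, "item_b": "", "value": cv})
        rows.append({"metric": "median_cv", "item_a": "", "item_b": "",
                     "value": self.median_cv})
        return pd.DataFrame(rows)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every present value by its base-2 logarithm.

    Rejects matrices already flagged log2 (double transform) and any
    non-positive present value, naming its location.
    """
    if m.log2_transformed:
        raise ValueError("matrix is already log2-transformed")
    values = m.data.to_numpy(dtype=float)
    bad = (values <= 0) & ~np.isnan(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive value {values[i, j]} at sample {m.data.index[i]!r}, "
            f"feature {m.data.columns[j]!r} cannot be log2-transformed"
        )
    return ExpressionMatrix(np.log2(m.data), log2_transformed=True)


def median_normalize(m: ExpressionMatrix, target: float = 0.0) -> ExpressionMatrix:
    """Additively shift each sample so its median over present features equals
    ``target`` (even counts use the mean of the two central order statistics)."""
    medians = m.data.median(axis=1, skipna=True)
    empty = medians.isna()
    if empty.any():
        raise ValueError(
            f"sample {m.data.index[empty][0]!r} has no present values to normalize"
        )
    shifted = m.data.sub(medians - target, axis=0)
    return ExpressionMatrix(shifted, log2_transformed=m.log2_transformed)


def filter_noise_features(
    m: ExpressionMatrix, min_observed_fraction: float = 0.5
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop features observed in fewer than ``min_observed_fraction`` of
    samples; the boundary is inclusive (a feature at exactly the threshold
    is kept).  Returns the filtered matrix and the removed feature list."""
    if not 0.0 <= min_observed_fraction <= 1.0:
        raise ValueError("min_observed_fraction must be in [0, 1]")
    observed = m.data.notna().sum(axis=0) / m.n_samples
    keep = observed >= min_observed_fraction
    removed = [f for f, k in keep.items() if not k]
    return ExpressionMatrix(m.data.loc[:, keep], m.log2_transformed), removed


def impute(m: ExpressionMatrix, method: str = "global_min", scale: float = 1.0) -> ExpressionMatrix:
    """Fill missing entries with a scaled minimum.

    global_min: scale x minimum over all present entries of the matrix;
    sample_min: scale x minimum over the sample's (row's) present entries;
    feature_min: scale x minimum of that feature across all samples
    (column-wise).  Present values are never altered.
    """
    if method == "none":
        return m.copy()
    if method not in IMPUTATION_METHODS:
        raise ValueError(f"unknown imputation method {method!r}")
    if scale <= 0:
        raise ValueError("imputation scale must be > 0")
    data = m.data.copy()
    mask = data.isna()
    if not mask.to_numpy().any():
        return ExpressionMatrix(data, m.log2_transformed)
    if method == "global_min":
        global_min = data.min().min()
        if pd.isna(global_min):
            raise ValueError("cannot impute an all-missing matrix")
        fill = pd.DataFrame(scale * global_min, index=data.index, columns=data.columns)
    elif method == "sample_min":
        row_min = data.min(axis=1)
        bad = row_min.isna() & mask.any(axis=1)
        if bad.any():
            raise ValueError(
                f"sample {data.index[bad][0]!r} is all-missing; filter before sample_min"
            )
        fill = pd.DataFrame(
            np.broadcast_to((scale * row_min).to_numpy()[:, None], data.shape),
            index=data.index, columns=data.columns,
        )
    else:  # feature_min
        col_min = data.min(axis=0)
        bad = col_min.isna() & mask.any(axis=0)
        if bad.any():
            raise ValueError(
                f"feature {data.columns[bad][0]!r} is all-missing; filter before feature_min"
            )
        fill = pd.DataFrame(
            np.broadcast_to((scale * col_min).to_numpy()[None, :], data.shape),
            index=data.index, columns=data.columns,
        )
    return ExpressionMatrix(data.where(~mask, fill), m.log2_transformed)


def qc_replicate_report(
    m: ExpressionMatrix,
    qc_sample_ids: list[str],
    correlation_method: str = "pearson",
    cv_scale: str = "linear",
) -> QCReport:
    """Correlate QC replicate samples pairwise and compute per-feature CVs.

    Each pair is correlated over features present in both samples; pairs
    with < 3 co-present features get an undefined r excluded from the mean.
    CV is sample standard deviation over mean, computed per feature across
    the QC samples after unlogging to the linear scale (``cv_scale="log2"``
    skips the unlogging).
    """
    unknown = [s for s in qc_sample_ids if s not in m.data.index]
    if unknown:
        raise ValueError(f"unknown QC sample ids: {unknown}")
    if len(qc_sample_ids) < 2:
        raise ValueError("need at least 2 QC samples")
    if correlation_method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {correlation_method!r}")

    sub = m.data.loc[qc_sample_ids]
    n = len(qc_sample_ids)
    grid = np.full((n, n), np.nan)
    np.fill_diagonal(grid, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            a = sub.iloc[i]
            b = sub.iloc[j]
            both = a.notna() & b.notna()
            if both.sum() < 3:
                continue
            if correlation_method == "pearson":
                r = stats.pearsonr(a[both], b[both]).statistic
            else:
                r = stats.spearmanr(a[both], b[both]).statistic
            grid[i, j] = grid[j, i] = r
    corr = pd.DataFrame(grid, index=qc_sample_ids, columns=qc_sample_ids)
    upper = grid[np.triu_indices(n, k=1)]
    mean_r = float(np.nanmean(upper)) if np.isfinite(upper).any() else float("nan")

    linear = np.power(2.0, sub) if cv_scale == "linear" else sub
    means = linear.mean(axis=0, skipna=True)
    sds = linear.std(axis=0, ddof=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sds / means
    cv = cv.replace([np.inf, -np.inf], np.nan)
    finite = cv.dropna()
    median_cv = float(finite.median()) if len(finite) else float("nan")
    return QCReport(
        qc_sample_ids=list(qc_sample_ids),
        pairwise_correlations=corr,
        mean_correlation=mean_r,
        per_feature_cv=cv,
        median_cv=median_cv,
        correlation_method=correlation_method,
        cv_scale=cv_scale,
    )
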