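"""Phenotype-associated feature discovery: differential expression,
PCA with contribution-score ranking, and hierarchical feature clustering.

Differential expression compares two phenotype groups per feature with a
t-test or Wilcoxon variant, adjusts p-values by the Benjamini-Hochberg
step-up, and calls a feature significant when the adjusted p falls below
0.01 and the (median-based) fold change exceeds 1.5.

The PCA contribution score ranks features across retained principal
components: with explained variance ratios VR_i and loadings V_ij
(component i, feature j),

    S_j = sum_i VR_i * |V_ij| / sum_j' |V_ij'| ,

so each component distributes its variance ratio over the features in
proportion to their absolute loadings, and sum_j S_j = sum_i VR_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .core_data import CATEGORICAL, ExpressionMatrix, PhenotypeTable

__all__ = [
    "DEConfig",
    "DEResult",
    "PCAResult",
    "ClusterResult",
    "differential_expression",
    "benjamini_hochberg",
    "pca_contribution",
    "cluster_features",
]

DE_TESTS = ("student_t", "wilcoxon_ranksum", "paired_t", "wilcoxon_signed_rank")
PAIRED_TESTS = ("paired_t", "wilcoxon_signed_rank")

#: Largest per-group size at which the rank-sum test uses exact enumeration
#: (only when the pooled data has no ties).
EXACT_RANKSUM_MAX_N = 10


@dataclass
class DEConfig:
    """Differential-expression settings.

    group_phenotype / group1 / group2 pick the contrast (e.g.
    Pathological_Status, Tumor vs Non-Tumor); log2 fold change is
    median(group1) - median(group2).  ``welch`` selects the unequal-variance
    t form (default); ``use_median_fc=False`` switches to mean-based FC.
    """

    group_phenotype: str = "Pathological_Status"
    group1: str = "Tumor"
    group2: str = "Non-Tumor"
    test: str = "student_t"
    fc_threshold: float = 1.5
    adj_p_threshold: float = 0.01
    paired_by: str | None = None
    welch: bool = True
    use_median_fc: bool = True

    def __post_init__(self) -> None:
        if self.test not in DE_TESTS:
            raise ValueError(f"test must be one of {DE_TESTS}, got {self.test!r}")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if not 0 < self.adj_p_threshold < 1:
            raise ValueError("adj_p_threshold must be in (0, 1)")
        if self.test in PAIRED_TESTS and self.paired_by is None:
            raise ValueError(f"{self.test} requires paired_by")


@dataclass
class DEResult:
    """Per-feature differential-expression outcomes.

    ``table`` columns: feature, n1, n2, median_g1, median_g2, log2_fc,
    fold_change, raw_p, adj_p, direction (up/down/ns), tested.  Features
    with < 2 observations in either group are reported untested (NaN p,
    direction ns), never silently dropped.
    """

    table: pd.DataFrame
    config: DEConfig

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "ns"]

    def features_by_direction(self, direction: str) -> list[str]:
        return list(self.table.loc[self.table["direction"] == direction, "feature"])


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    Sort ascending; adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    NaN entries (untested features) are passed through and excluded from m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    tested = ~np.isnan(p)
    pt = p[tested]
    if ((pt < 0) | (pt > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pt.size
    if m == 0:
        return out
    order = np.argsort(pt, kind="stable")
    ranked = pt[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[tested] = restored
    return out


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact enumeration for small tie-free groups,
    normal approximation with continuity and tie correction otherwise."""
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and len(x) <= EXACT_RANKSUM_MAX_N and len(y) <= EXACT_RANKSUM_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _raw_p(x: np.ndarray, y: np.ndarray, cfg: DEConfig) -> float:
    if cfg.test == "student_t":
        return float(stats.ttest_ind(x, y, equal_var=not cfg.welch).pvalue)
    if cfg.test == "wilcoxon_ranksum":
        return _ranksum_p(x, y)
    if cfg.test == "paired_t":
        return float(stats.ttest_rel(x, y).pvalue)
    # wilcoxon_signed_rank
    d = x - y
    if np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(x, y).pvalue)


def _paired_arrays(
    m: ExpressionMatrix, p: PhenotypeTable, cfg: DEConfig, g1_ids: list[str], g2_ids: list[str]
) -> tuple[list[str], list[str]]:
    """Order the two groups by the pairing key; orphans are a hard error."""
    pair_col = p.column(cfg.paired_by)
    g1_pairs = {pair_col[s]: s for s in g1_ids if pd.notna(pair_col[s])}
    g2_pairs = {pair_col[s]: s for s in g2_ids if pd.notna(pair_col[s])}
    orphans = sorted(set(g1_pairs) ^ set(g2_pairs))
    if orphans:
        raise ValueError(f"unmatched pair keys for paired test: {orphans}")
    keys = sorted(g1_pairs)
    return [g1_pairs[k] for k in keys], [g2_pairs[k] for k in keys]


def differential_expression(
    m: ExpressionMatrix, p: PhenotypeTable, cfg: DEConfig
) -> DEResult:
    """Two-group differential expression over every feature of the matrix."""
    pheno = p.column(cfg.group_phenotype)
    levels = set(map(str, pheno.dropna().unique()))
    for level in (cfg.group1, cfg.group2):
        if level not in levels:
            raise ValueError(
                f"group level {level!r} not found in phenotype "
                f"{cfg.group_phenotype!r} (levels: {sorted(levels)})"
            )
    shared = [s for s in m.sample_ids if s in pheno.index]
    g1_ids = [s for s in shared if str(pheno[s]) == cfg.group1]
    g2_ids = [s for s in shared if str(pheno[s]) == cfg.group2]
    paired = cfg.test in PAIRED_TESTS
    if paired:
        g1_ids, g2_ids = _paired_arrays(m, p, cfg, g1_ids, g2_ids)

    g1 = m.data.loc[g1_ids]
    g2 = m.data.loc[g2_ids]
    log2_fc_thr = np.log2(cfg.fc_threshold)
    rows = []
    for feature in m.feature_ids:
        a_all = g1[feature].to_numpy(dtype=float)
        b_all = g2[feature].to_numpy(dtype=float)
        if paired:
            ok = ~np.isnan(a_all) & ~np.isnan(b_all)
            a, b = a_all[ok], b_all[ok]
        else:
            a = a_all[~np.isnan(a_all)]
            b = b_all[~np.isnan(b_all)]
        tested = len(a) >= 2 and len(b) >= 2
        if tested:
            if cfg.use_median_fc:
                loc1, loc2 = float(np.median(a)), float(np.median(b))
            else:
                loc1, loc2 = float(np.mean(a)), float(np.mean(b))
            log2_fc = loc1 - loc2
            raw_p = _raw_p(a, b, cfg)
        else:
            loc1 = float(np.median(a)) if len(a) else np.nan
            loc2 = float(np.median(b)) if len(b) else np.nan
            log2_fc = np.nan
            raw_p = np.nan
        rows.append({
            "feature": feature, "n1": len(a), "n2": len(b),
            "median_g1": loc1, "median_g2": loc2,
            "log2_fc": log2_fc,
            "fold_change": float(2.0 ** log2_fc) if np.isfinite(log2_fc) else np.nan,
            "raw_p": raw_p,
        })
    table = pd.DataFrame(rows)
    table["adj_p"] = benjamini_hochberg(table["raw_p"].to_numpy())
    table["tested"] = table["raw_p"].notna()
    sig = table["adj_p"] < cfg.adj_p_threshold
    direction = np.where(
        sig & (table["log2_fc"] > log2_fc_thr), "up",
        np.where(sig & (table["log2_fc"] < -log2_fc_thr), "down", "ns"),
    )
    table["direction"] = direction
    return DEResult(table=table, config=cfg)


@dataclass
class PCAResult:
    """PCA decomposition with per-feature contribution scores.

    ``loadings`` is components x features; ``contribution`` is the S_j
    series sorted descending; ``top_features`` the first ``top_k`` of it;
    ``top_per_component`` maps each PC to its 10 largest-|loading| features.
    """

    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    contribution: pd.Series
    top_features: list[str]
    top_per_component: dict[str, list[str]]

    def contribution_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.contribution.index,
            "contribution_score": self.contribution.to_numpy(),
            "rank": np.arange(1, len(self.contribution) + 1),
            "selected": [f in set(self.top_features) for f in self.contribution.index],
        })


def pca_contribution(
    m: ExpressionMatrix,
    n_components: int = 10,
    top_k: int = 100,
    scale_features: bool = False,
    per_component_top: int = 10,
) -> PCAResult:
    """PCA (singular value decomposition of the centered matrix) plus the
    contribution score S_j ranking features across retained components.

    Features are mean-centered across samples; z-score scaling is optional
    since log2 data are already on a comparable scale.  ``n_components``
    beyond min(n_samples - 1, n_features) is clipped.
    """
    if m.missing_mask().to_numpy().any():
        raise ValueError("matrix contains missing values; impute before PCA")
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples for PCA")
    X = m.data.to_numpy(dtype=float)
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("matrix is constant; PCA is undefined")
    if scale_features:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    max_rank = min(m.n_samples - 1, m.n_features)
    k = min(n_components, max_rank)
    if k < n_components:
        warnings.warn(
            f"n_components={n_components} exceeds the matrix rank bound; "
            f"clipped to {k}",
            stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    vr = pca.explained_variance_ratio_
    comp_names = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(pca.components_, index=comp_names, columns=m.feature_ids)

    abs_load = loadings.abs()
    row_sums = abs_load.sum(axis=1)
    contrib = (abs_load.div(row_sums, axis=0)).mul(vr, axis=0).sum(axis=0)
    contrib = contrib.sort_values(ascending=False, kind="stable")
    top_features = list(contrib.index[: min(top_k, len(contrib))])
    top_per_component = {
        pc: list(abs_load.loc[pc].sort_values(ascending=False, kind="stable")
                 .index[:per_component_top])
        for pc in comp_names
    }
    return PCAResult(
        explained_variance_ratio=vr,
        loadings=loadings,
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=comp_names),
        contribution=contrib,
        top_features=top_features,
        top_per_component=top_per_component,
    )


@dataclass
class ClusterResult:
    """Flat cut of a hierarchical feature clustering.

    ``assignments`` maps feature -> cluster id in 1..k, ids renumbered so
    cluster 1 contains the first feature in matrix order; ``linkage`` is the
    scipy merge record.
    """

    assignments: pd.Series
    linkage: np.ndarray
    k: int

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.assignments.index,
                             "cluster": self.assignments.to_numpy()})


def cluster_features(m: ExpressionMatrix, k: int) -> ClusterResult:
    """Ward hierarchical clustering of z-scored feature profiles, cut to k.

    Each feature is z-scored across samples (sample sd) first so clusters
    group shared alteration patterns, not absolute abundance.  Constant
    features cannot be z-scored and are rejected with a named list.
    """
    if m.missing_mask().to_numpy().any():
        raise ValueError("matrix contains missing values; impute before clustering")
    if not 1 <= k <= m.n_features:
        raise ValueError(f"k must be in [1, {m.n_features}], got {k}")
    profiles = m.data.to_numpy(dtype=float).T  # features x samples
    sd = profiles.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        names = [m.feature_ids[i] for i in np.flatnonzero(constant)]
        raise ValueError(f"constant features cannot be z-scored: {names[:10]}")
    z = (profiles - profiles.mean(axis=1, keepdims=True)) / sd[:, None]
    link = hierarchy.linkage(z, method="ward")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    # renumber cluster ids by first appearance in feature order (deterministic)
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    renumbered = np.array([remap[lab] for lab in labels])
    return ClusterResult(
        assignments=pd.Series(renumbered, index=m.feature_ids, name="cluster"),
        linkage=link,
        k=k,
    )
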