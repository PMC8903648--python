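"""Per-feature phenotype association: correlation screen, unpenalized
logistic regression, and rank-based ROC/AUC.

A feature is flagged phenotype-associated when its correlation p-value with
the (0/1-encoded) categorical phenotype falls below alpha (default 0.05).
The logistic model P(y=1|x) = 1/(1+exp(-(a+bx))) is fit by iteratively
reweighted least squares without regularization; complete separation is
flagged rather than penalized away, since the capped iterate still ranks
samples monotonically in x so the ROC/AUC remains valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .core_data import CATEGORICAL, ExpressionMatrix, PhenotypeTable
from .profiling import encode_categorical

__all__ = [
    "LogisticFit",
    "feature_phenotype_correlation",
    "logistic_fit",
    "roc_auc",
    "associate_features",
]

MAX_IRLS_ITER = 100
IRLS_TOL = 1e-8


def feature_phenotype_correlation(
    m: ExpressionMatrix,
    p: PhenotypeTable,
    phenotype: str,
    alpha: float = 0.05,
    method: str = "pearson",
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Correlate each feature with a categorical phenotype.

    Binary phenotypes give one contrast (Pearson against the 0/1 encoding,
    i.e. the point-biserial correlation); multi-level phenotypes are handled
    one-vs-rest with one row per feature per contrast.  Features constant
    over the shared samples get undefined r and are never counted
    associated.
    """
    if p.kind(phenotype) != CATEGORICAL:
        raise ValueError(f"phenotype {phenotype!r} is not categorical")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    col = p.column(phenotype)
    levels = sorted(map(str, col.dropna().unique()))
    if len(levels) < 2:
        raise ValueError(f"phenotype {phenotype!r} has < 2 levels")
    if len(levels) == 2:
        encoded, mapping = encode_categorical(col)
        positive = [lvl for lvl, code in mapping.items() if code == 1][0]
        contrasts = [(positive, encoded)]
    else:
        contrasts = []
        for level in levels:
            ovr = col.map(lambda v: np.nan if pd.isna(v) else float(str(v) == level))
            contrasts.append((level, ovr.astype(float)))

    feats = features if features is not None else m.feature_ids
    rows = []
    for contrast, y in contrasts:
        for feature in feats:
            x = m.data[feature]
            both = x.notna() & y.notna()
            xv, yv = x[both].to_numpy(dtype=float), y[both].to_numpy(dtype=float)
            r = pv = np.nan
            if len(xv) >= 3 and np.ptp(xv) > 0 and np.ptp(yv) > 0:
                if method == "pearson":
                    res = stats.pearsonr(xv, yv)
                else:
                    res = stats.spearmanr(xv, yv)
                r, pv = float(res.statistic), float(res.pvalue)
            rows.append({
                "feature": feature, "contrast": contrast,
                "r": r, "p": pv,
                "associated": bool(pv < alpha) if np.isfinite(pv) else False,
                "n": int(len(xv)),
            })
    return pd.DataFrame(rows)


@dataclass
class LogisticFit:
    """Result of a univariate logistic fit."""

    intercept: float
    slope: float
    probabilities: np.ndarray
    converged: bool
    separated: bool
    n_iter: int
    log_likelihood: float


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: sum y*eta - log(1+e^eta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_fit(x, y) -> LogisticFit:
    """Maximum-likelihood univariate logistic regression via IRLS.

    Stops when the log-likelihood improves by < 1e-8 or after 100
    iterations; non-convergence (the signature of complete or quasi
    separation, where the MLE is at infinity) returns the last iterate with
    ``separated=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise ValueError("need >= 3 samples per class")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: logistic fit is not meaningful")

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll = _log_likelihood(y, X @ beta)
    converged = False
    it = 0
    for it in range(1, MAX_IRLS_ITER + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(X.T @ WX, X.T @ (w * z), rcond=None)
        new_ll = _log_likelihood(y, np.clip(X @ beta, -30, 30))
        if abs(new_ll - ll) < IRLS_TOL:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    probs = expit(np.clip(X @ beta, -30, 30))
    # complete separation: in the univariate monotone model the classes are
    # separable iff their x-ranges do not overlap; the MLE is then at
    # infinity and the returned iterate is only a (monotone) surrogate
    separated = (not converged) or (
        min(x[y == 1]) > max(x[y == 0]) or max(x[y == 1]) < min(x[y == 0])
    )
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        probabilities=probs,
        converged=converged,
        separated=separated,
        n_iter=it,
        log_likelihood=ll,
    )


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """Rank-based AUC (Mann-Whitney with midranks for ties) and ROC points.

    AUC = (sum of positive ranks - n_pos(n_pos+1)/2) / (n_pos * n_neg);
    ROC points are emitted at every distinct score threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC")
    ranks = stats.rankdata(scores)  # midranks for ties
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    points = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        thr = sorted_scores[i]
        while i < n and sorted_scores[i] == thr:
            if sorted_pos[i]:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append({"threshold": float(thr), "fpr": fp / n_neg, "tpr": tp / n_pos})
    return float(auc), pd.DataFrame(points)


def associate_features(
    m: ExpressionMatrix,
    p: PhenotypeTable,
    phenotype: str,
    features: list[str] | None = None,
    alpha: float = 0.05,
    correlation_method: str = "pearson",
) -> pd.DataFrame:
    """Full single-feature association screen for a binary phenotype:
    correlation + flag, logistic fit, and in-sample AUC per feature.

    Features whose logistic fit is infeasible (e.g. constant expression
    over the shared samples) keep NaN model fields but remain in the table.
    """
    corr = feature_phenotype_correlation(
        m, p, phenotype, alpha=alpha, method=correlation_method, features=features
    )
    if corr["contrast"].nunique() > 1:
        raise ValueError(
            "associate_features expects a binary phenotype; run "
            "feature_phenotype_correlation per contrast for multi-level ones"
        )
    encoded, _ = encode_categorical(p.column(phenotype))
    rows = []
    for _, crow in corr.iterrows():
        feature = crow["feature"]
        x = m.data[feature]
        both = x.notna() & encoded.notna()
        xv = x[both].to_numpy(dtype=float)
        yv = encoded[both].to_numpy(dtype=float)
        intercept = slope = auc = np.nan
        separated = False
        try:
            fit = logistic_fit(xv, yv)
            intercept, slope, separated = fit.intercept, fit.slope, fit.separated
            auc, _ = roc_auc(fit.probabilities, yv)
        except ValueError:
            pass
        rows.append({
            "feature": feature, "contrast": crow["contrast"],
            "r": crow["r"], "p": crow["p"], "associated": crow["associated"],
            "intercept": intercept, "slope": slope, "separated": separated,
            "auc": auc, "n": crow["n"],
        })
    return pd.DataFrame(rows)
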