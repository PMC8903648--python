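"""Phenotype cohort profiling and pairwise phenotype correlation.

Profiling reports the population of samples in each level of every
categorical phenotype and summary statistics of every numerical phenotype.
Pairwise correlation (Spearman by default) reveals dependencies between
phenotypes after encoding categorical levels as ordinals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CATEGORICAL, NUMERICAL, PhenotypeTable

__all__ = [
    "PhenotypeProfile",
    "PhenotypeCorrelationMatrix",
    "profile_phenotypes",
    "encode_categorical",
    "correlate_phenotypes",
]

MISSING_LABEL = "<missing>"


@dataclass
class PhenotypeProfile:
    """Long-format cohort composition table.

    Categorical phenotypes contribute one row per level plus a missing
    count; numerical phenotypes contribute n/mean/median/min/max/missing
    rows computed over non-missing values.
    """

    table: pd.DataFrame  # columns: phenotype, kind, item, value
    n_samples: int

    def counts(self, phenotype: str) -> dict[str, float]:
        rows = self.table[self.table["phenotype"] == phenotype]
        return dict(zip(rows["item"], rows["value"]))


def profile_phenotypes(p: PhenotypeTable) -> PhenotypeProfile:
    n = len(p.sample_ids)
    rows: list[dict] = []
    for name in p.phenotype_names:
        col = p.column(name)
        kind = p.kind(name)
        missing = int(col.isna().sum())
        if kind == CATEGORICAL:
            counts = col.dropna().value_counts()
            for level in sorted(counts.index):
                rows.append({"phenotype": name, "kind": kind,
                             "item": str(level), "value": float(counts[level])})
            rows.append({"phenotype": name, "kind": kind,
                         "item": MISSING_LABEL, "value": float(missing)})
        else:
            present = col.dropna().astype(float)
            stats_map = {
                "n": float(len(present)),
                "mean": float(present.mean()) if len(present) else float("nan"),
                "median": float(present.median()) if len(present) else float("nan"),
                "min": float(present.min()) if len(present) else float("nan"),
                "max": float(present.max()) if len(present) else float("nan"),
                MISSING_LABEL: float(missing),
            }
            for item, value in stats_map.items():
                rows.append({"phenotype": name, "kind": kind, "item": item, "value": value})
    return PhenotypeProfile(pd.DataFrame(rows), n_samples=n)


def encode_categorical(values: pd.Series) -> tuple[pd.Series, dict[str, int]]:
    """Map categorical levels to 0,1,2,... in lexicographic level order.

    Missing entries stay missing.  The encoding map is returned so the
    (order-dependent, for >2 levels) choice is auditable.
    """
    levels = sorted(values.dropna().unique())
    if not levels:
        raise ValueError("cannot encode an all-missing categorical phenotype")
    mapping = {str(level): code for code, level in enumerate(levels)}
    encoded = values.map(lambda v: mapping[str(v)] if pd.notna(v) else np.nan)
    return encoded.astype(float), mapping


@dataclass
class PhenotypeCorrelationMatrix:
    """Symmetric phenotype x phenotype correlation grid with p-values.

    Cells where a pair shares < 3 samples or one vector is constant are
    undefined (NaN), not fabricated.  ``encodings`` records the ordinal
    codes used for each categorical phenotype.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    encodings: dict[str, dict[str, int]]
    method: str

    def to_long_frame(self) -> pd.DataFrame:
        names = list(self.r.index)
        rows = []
        for i, a in enumerate(names):
            for b in names[i:]:
                rows.append({"phenotype_a": a, "phenotype_b": b,
                             "r": self.r.loc[a, b], "p": self.p.loc[a, b]})
        return pd.DataFrame(rows)


def correlate_phenotypes(p: PhenotypeTable, method: str = "spearman") -> PhenotypeCorrelationMatrix:
    """Pairwise correlation of all phenotypes over shared non-missing samples.

    Categorical phenotypes are ordinal-encoded first.  Spearman is the
    default because the encodings are ordinal at best; Pearson selectable.
    p-values use the t-approximation of the chosen correlation.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    names = p.phenotype_names
    if len(names) < 2:
        raise ValueError("need at least 2 phenotypes to correlate")
    encoded: dict[str, pd.Series] = {}
    encodings: dict[str, dict[str, int]] = {}
    for name in names:
        col = p.column(name)
        if p.kind(name) == CATEGORICAL:
            if col.dropna().empty:
                encoded[name] = col.astype(float) * np.nan
                encodings[name] = {}
            else:
                encoded[name], encodings[name] = encode_categorical(col)
        else:
            encoded[name] = col.astype(float)
    k = len(names)
    r = np.full((k, k), np.nan)
    pv = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(pv, 0.0)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = encoded[names[i]], encoded[names[j]]
            both = a.notna() & b.notna()
            if both.sum() < 3:
                continue
            x, y = a[both].to_numpy(), b[both].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            if method == "spearman":
                res = stats.spearmanr(x, y)
            else:
                res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            pv[i, j] = pv[j, i] = res.pvalue
    return PhenotypeCorrelationMatrix(
        r=pd.DataFrame(r, index=names, columns=names),
        p=pd.DataFrame(pv, index=names, columns=names),
        encodings=encodings,
        method=method,
    )
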