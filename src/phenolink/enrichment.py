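"""Over-representation analysis (ORA) of feature sets against GMT gene-set
collections.

Query features (gene symbols or glycoform identifiers, which collapse to
their gene) are tested against each gene set restricted to the measured
background: with background size N, restricted set size K, query size n and
overlap k, the enrichment p-value is the hypergeometric upper tail
P(X >= k), BH-adjusted across all tested sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .core_data import GlycoformParseError, parse_glycoform
from .feature_discovery import benjamini_hochberg

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "features_to_genes",
    "ora",
]


@dataclass
class GeneSetCollection:
    """Named gene sets loaded from a GMT file (name, description, members)."""

    name: str
    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str, name: str | None = None) -> GeneSetCollection:
    """Read a tab-separated GMT file: set name, description, member genes.

    Case is preserved; duplicate members within a set are deduplicated;
    a duplicate set name or a line with < 3 fields is a hard error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            set_name, description, *members = fields
            if set_name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {set_name!r}")
            members = [g for g in members if g.strip()]
            sets[set_name] = frozenset(members)
            descriptions[set_name] = description
    if not sets:
        warnings.warn(f"GMT file {path} contains no gene sets", stacklevel=2)
    return GeneSetCollection(
        name=name or str(path), sets=sets, descriptions=descriptions, source=str(path)
    )


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for set_name, members in collection.sets.items():
            desc = collection.descriptions.get(set_name, "")
            fh.write("\t".join([set_name, desc, *sorted(members)]) + "\n")


def features_to_genes(features) -> set[str]:
    """Collapse feature ids to gene symbols.

    Glycoform identifiers map to their gene field; anything else passes
    through unchanged.  The result is a deduplicated set.
    """
    genes: set[str] = set()
    for fid in features:
        try:
            genes.add(parse_glycoform(str(fid)).gene)
        except GlycoformParseError:
            genes.add(str(fid))
    return genes


def ora(
    query: set[str],
    background: set[str],
    collection: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 2000,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set.

    The background is normally the genes measured in the input matrix.
    Query symbols outside the background are dropped with a warning.  Sets
    are restricted to the background first and kept only if the restricted
    size K satisfies min_size <= K <= max_size and K < N.  One-sided
    enrichment p = P(X >= k) via the hypergeometric survival function; BH
    across all tested sets; rows sorted by adjusted p ascending.
    """
    query = set(query)
    background = set(background)
    if not background:
        raise ValueError("empty background")
    stray = query - background
    if stray:
        warnings.warn(
            f"{len(stray)} query symbols outside the background were dropped",
            stacklevel=2,
        )
        query = query & background
    if not query:
        raise ValueError("empty query after background restriction")
    N = len(background)
    n = len(query)
    rows = []
    for set_name, members in collection.sets.items():
        restricted = members & background
        K = len(restricted)
        if K < min_size or K > max_size or K >= N:
            continue
        overlap = sorted(query & restricted)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "set": set_name,
            "description": collection.descriptions.get(set_name, ""),
            "overlap": k, "set_size": K, "query_size": n, "background_size": N,
            "p": min(p, 1.0),
            "overlap_genes": ";".join(overlap),
        })
    result = pd.DataFrame(rows)
    if result.empty:
        return pd.DataFrame(columns=[
            "set", "description", "overlap", "set_size", "query_size",
            "background_size", "p", "adj_p", "overlap_genes",
        ])
    result["adj_p"] = benjamini_hochberg(result["p"].to_numpy())
    result = result.sort_values(
        ["adj_p", "p", "set"], kind="stable", ignore_index=True
    )
    return result[["set", "description", "overlap", "set_size", "query_size",
                   "background_size", "p", "adj_p", "overlap_genes"]]
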