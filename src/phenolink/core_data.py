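"""Domain types and I/O for wide-format omics matrices, phenotype tables,
intact-glycopeptide (glycoform) identifiers, and annotation databases.

The expression matrix is a samples x features grid of log2 abundances saved
as delimited text: sample names are the row indices, feature names (gene
symbols or glycoform identifiers) are the column labels.  Phenotype tables
use the same layout with each column label suffixed ``(Categorical)`` or
``(Numerical)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PhenotypeTable",
    "GlycoformID",
    "AnnotationTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_phenotype_table",
    "write_phenotype_table",
    "parse_glycoform",
    "format_glycoform",
    "read_annotation_table",
    "annotate_features",
    "DEFAULT_MISSING_SENTINELS",
]

#: Cell contents treated as missing when reading delimited matrices
#: (compared case-insensitively).  The empty cell is always missing.
DEFAULT_MISSING_SENTINELS = ("", "na", "nan")

CATEGORICAL = "categorical"
NUMERICAL = "numerical"

_PHENOTYPE_TAG_RE = re.compile(r"^(?P<name>.*?)\s*\((?P<tag>Categorical|Numerical)\)\s*$")
_GLYCAN_TOKEN_RE = re.compile(r"([A-Za-z]+)([0-9]+)")
_GLYCAN_FULL_RE = re.compile(r"^(?:[A-Za-z]+[0-9]+)+$")
_PEPTIDE_RE = re.compile(r"^[A-Za-z]+$")


class MatrixFormatError(ValueError):
    """Raised when a delimited matrix or phenotype file violates the format contract."""


class GlycoformParseError(ValueError):
    """Raised when a glycoform identifier cannot be parsed."""


def _infer_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass
class ExpressionMatrix:
    """Samples x features grid of (usually log2) abundances.

    ``data`` is a float DataFrame indexed by sample id with feature ids as
    columns; missing measurements are NaN.  Present entries must be finite.
    """

    data: pd.DataFrame
    log2_transformed: bool = True

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise MatrixFormatError(f"duplicate sample id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise MatrixFormatError(f"duplicate feature id: {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if np.isinf(values).any():
            i, j = np.argwhere(np.isinf(values))[0]
            raise MatrixFormatError(
                f"non-finite value at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.log2_transformed)


@dataclass
class PhenotypeTable:
    """Per-sample clinical variables, each tagged categorical or numerical.

    ``data`` holds stripped phenotype names as columns; ``kinds`` maps each
    phenotype name to ``"categorical"`` or ``"numerical"``.  Numerical
    columns are floats, categorical columns strings; missing values are NaN.
    """

    data: pd.DataFrame
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise MatrixFormatError(f"duplicate sample id: {dup!r}")
        for name in self.data.columns:
            kind = self.kinds.get(name)
            if kind not in (CATEGORICAL, NUMERICAL):
                raise MatrixFormatError(
                    f"phenotype {name!r} has unknown kind {kind!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def phenotype_names(self) -> list[str]:
        return list(self.data.columns)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown phenotype {name!r}")
        return self.data[name]

    def kind(self, name: str) -> str:
        if name not in self.kinds:
            raise KeyError(f"unknown phenotype {name!r}")
        return self.kinds[name]


@dataclass(frozen=True)
class GlycoformID:
    """Structured intact-glycopeptide identifier.

    The textual form is
    ``GeneName_PeptideStartSite_PeptideSequence_GlycositeNumber_GlycositePosition_Glycancomposition``
    e.g. ``HYOU1_869_NATLAEQAK_1_869_N2H9``: gene HYOU1, tryptic peptide
    NATLAEQAK starting at protein position 869, carrying one glycosite at
    position 869 with glycan composition N2H9 (2 HexNAc, 9 Hex).
    """

    gene: str
    peptide_start: int
    peptide_sequence: str
    glycosite_number: int
    glycosite_position: int
    glycan_composition: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise GlycoformParseError("empty gene symbol")
        if not _PEPTIDE_RE.match(self.peptide_sequence):
            raise GlycoformParseError(
                f"peptide sequence {self.peptide_sequence!r} is not amino-acid text"
            )
        if self.glycosite_number < 1:
            raise GlycoformParseError(
                f"glycosite number must be >= 1, got {self.glycosite_number}"
            )
        if self.peptide_start < 1:
            raise GlycoformParseError(
                f"peptide start must be >= 1, got {self.peptide_start}"
            )
        lo = self.peptide_start
        hi = self.peptide_start + len(self.peptide_sequence) - 1
        if not (lo <= self.glycosite_position <= hi):
            raise GlycoformParseError(
                f"glycosite position {self.glycosite_position} outside "
                f"peptide span [{lo}, {hi}]"
            )
        if not _GLYCAN_FULL_RE.match(self.glycan_composition):
            raise GlycoformParseError(
                f"malformed glycan composition {self.glycan_composition!r}"
            )
        for code, count in _GLYCAN_TOKEN_RE.findall(self.glycan_composition):
            if int(count) < 1:
                raise GlycoformParseError(
                    f"glycan token {code}{count} has non-positive count"
                )

    def glycan_counts(self) -> dict[str, int]:
        """Monosaccharide code -> count, e.g. N2H9 -> {'N': 2, 'H': 9}."""
        counts: dict[str, int] = {}
        for code, count in _GLYCAN_TOKEN_RE.findall(self.glycan_composition):
            counts[code] = counts.get(code, 0) + int(count)
        return counts

    def __str__(self) -> str:
        return format_glycoform(self)


def parse_glycoform(id_text: str) -> GlycoformID:
    """Parse an underscore-delimited glycoform identifier.

    Gene symbols may themselves contain underscores; peptide sequences and
    glycan compositions cannot.  The five trailing fields are therefore
    split from the right and the gene is everything before the peptide
    start-site token.
    """
    tokens = id_text.split("_")
    if len(tokens) < 6:
        raise GlycoformParseError(
            f"{id_text!r}: expected >= 6 underscore-delimited tokens, got {len(tokens)}"
        )
    glycan = tokens[-1]
    pos_text = tokens[-2]
    num_text = tokens[-3]
    peptide = tokens[-4]
    start_text = tokens[-5]
    gene = "_".join(tokens[:-5])
    try:
        start = int(start_text)
        number = int(num_text)
        position = int(pos_text)
    except ValueError as exc:
        raise GlycoformParseError(f"{id_text!r}: non-integer coordinate field: {exc}") from None
    try:
        return GlycoformID(gene, start, peptide, number, position, glycan)
    except GlycoformParseError as exc:
        raise GlycoformParseError(f"{id_text!r}: {exc}") from None


def format_glycoform(g: GlycoformID) -> str:
    return (
        f"{g.gene}_{g.peptide_start}_{g.peptide_sequence}_"
        f"{g.glycosite_number}_{g.glycosite_position}_{g.glycan_composition}"
    )


def is_glycoform(id_text: str) -> bool:
    try:
        parse_glycoform(id_text)
        return True
    except GlycoformParseError:
        return False


def _parse_cells(raw: pd.DataFrame, sentinels: tuple[str, ...]) -> pd.DataFrame:
    """Convert a string-valued DataFrame to floats, mapping sentinels to NaN."""
    lowered = {s.lower() for s in sentinels} | {""}
    out = np.empty(raw.shape, dtype=float)
    values = raw.to_numpy(dtype=object)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = values[i, j]
            text = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if text.lower() in lowered:
                out[i, j] = np.nan
                continue
            try:
                out[i, j] = float(text)
            except ValueError:
                raise MatrixFormatError(
                    f"non-numeric cell {text!r} at sample {raw.index[i]!r}, "
                    f"column {raw.columns[j]!r}"
                ) from None
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def _check_header_unique(path: str, sep: str) -> None:
    """pandas silently renames duplicate header labels, so check them raw."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for label in header:
        if label in seen:
            raise MatrixFormatError(f"duplicate feature id: {label!r}")
        seen.add(label)


def read_expression_matrix(
    path: str,
    delimiter: str | None = None,
    sentinels: tuple[str, ...] = DEFAULT_MISSING_SENTINELS,
    log2_transformed: bool = True,
) -> ExpressionMatrix:
    """Read a wide-format expression matrix.

    Row 1 is the feature-name header, column 1 the sample names.  The
    delimiter is inferred from the extension (``.csv`` comma, else tab)
    unless given.  Empty cells and sentinel tokens become missing.
    """
    sep = _infer_delimiter(path, delimiter)
    _check_header_unique(path, sep)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    return ExpressionMatrix(_parse_cells(raw, sentinels), log2_transformed=log2_transformed)


def write_expression_matrix(m: ExpressionMatrix, path: str, delimiter: str | None = None) -> None:
    """Write the matrix as delimited text; missing entries become empty cells.

    Values are written with ``repr`` precision so a read-back reproduces
    every present value exactly.
    """
    sep = _infer_delimiter(path, delimiter)
    m.data.to_csv(path, sep=sep, na_rep="")


def read_phenotype_table(
    path: str,
    delimiter: str | None = None,
    sentinels: tuple[str, ...] = DEFAULT_MISSING_SENTINELS,
) -> PhenotypeTable:
    """Read a phenotype table whose column labels carry ``(Categorical)`` /
    ``(Numerical)`` suffix tags; the tag is stripped from the stored name."""
    sep = _infer_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    lowered = {s.lower() for s in sentinels} | {""}
    columns: dict[str, pd.Series] = {}
    kinds: dict[str, str] = {}
    for label in raw.columns:
        match = _PHENOTYPE_TAG_RE.match(str(label))
        if match is None:
            raise MatrixFormatError(
                f"phenotype column {label!r} lacks a (Categorical)/(Numerical) tag"
            )
        name = match.group("name").strip()
        kind = match.group("tag").lower()
        if name in kinds:
            raise MatrixFormatError(f"duplicate phenotype name {name!r}")
        col = raw[label].astype(str).str.strip()
        missing = col.str.lower().isin(lowered)
        if kind == NUMERICAL:
            parsed = pd.to_numeric(col.where(~missing), errors="coerce")
            bad = parsed.isna() & ~missing
            if bad.any():
                sample = raw.index[bad][0]
                raise MatrixFormatError(
                    f"numerical phenotype {name!r} has unparseable value "
                    f"{col[bad].iloc[0]!r} at sample {sample!r}"
                )
            columns[name] = parsed
        else:
            columns[name] = col.where(~missing)
        kinds[name] = kind
    data = pd.DataFrame(columns, index=raw.index)
    return PhenotypeTable(data, kinds)


def write_phenotype_table(p: PhenotypeTable, path: str, delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    tagged = p.data.copy()
    tagged.columns = [
        f"{name} ({'Categorical' if p.kinds[name] == CATEGORICAL else 'Numerical'})"
        for name in p.data.columns
    ]
    tagged.to_csv(path, sep=sep, na_rep="")


@dataclass
class AnnotationTable:
    """Keyed free-text annotation records with an optional URL template.

    ``key_columns`` name the join keys (``["gene"]`` or
    ``["gene", "glycosite_position"]``); ``url_template`` is a
    ``str.format``-style pattern over the key fields, e.g.
    ``https://www.uniprot.org/uniprotkb?query={gene}``.
    """

    records: pd.DataFrame
    key_columns: list[str]
    url_template: str | None = None
    name: str = "annotation"

    def __post_init__(self) -> None:
        for key in self.key_columns:
            if key not in self.records.columns:
                raise MatrixFormatError(
                    f"annotation db {self.name!r} missing key column {key!r}"
                )
            col = self.records[key]
            if col.isna().any() or (col.astype(str).str.strip() == "").any():
                raise MatrixFormatError(
                    f"annotation db {self.name!r} has empty values in key column {key!r}"
                )

    def render_url(self, key_values: dict[str, object]) -> str | None:
        if self.url_template is None:
            return None
        url = self.url_template.format(**{k: key_values[k] for k in self.key_columns})
        if "{" in url or "}" in url:
            raise MatrixFormatError(f"URL template left unfilled placeholders: {url!r}")
        return url


def read_annotation_table(
    path: str,
    key_columns: list[str],
    url_template: str | None = None,
    name: str = "annotation",
) -> AnnotationTable:
    records = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return AnnotationTable(records, list(key_columns), url_template, name)


def annotate_features(
    features: list[str],
    db: AnnotationTable,
    mode: str = "gene",
) -> pd.DataFrame:
    """Left-join feature ids onto an annotation database.

    ``gene`` mode keys on the feature id itself; ``glycosite`` mode parses
    each feature id as a glycoform and keys on (gene, glycosite_position),
    so two glycans at the same site share one annotation row.  Output order
    and row count match the input; unmatched rows carry ``matched=False``
    and empty annotation fields, matched rows a rendered ``url`` column.
    """
    if mode not in ("gene", "glycosite"):
        raise ValueError(f"unknown annotation mode {mode!r}")
    keys = []
    for fid in features:
        if mode == "gene":
            keys.append({"gene": fid})
        else:
            g = parse_glycoform(fid)
            keys.append({"gene": g.gene, "glycosite_position": g.glycosite_position})
    left = pd.DataFrame(keys)
    left.insert(0, "feature", features)
    right = db.records.copy()
    for key in db.key_columns:
        if key not in left.columns:
            raise MatrixFormatError(
                f"annotation mode {mode!r} does not supply key column {key!r}"
            )
        right[key] = right[key].astype(str)
        left[key] = left[key].astype(str)
    right = right.drop_duplicates(subset=db.key_columns, keep="first")
    merged = left.merge(right, how="left", on=db.key_columns, indicator=True)
    merged["matched"] = merged.pop("_merge") == "both"
    urls = []
    for _, row in merged.iterrows():
        if row["matched"] and db.url_template is not None:
            urls.append(db.render_url({k: row[k] for k in db.key_columns}))
        else:
            urls.append("")
    merged["url"] = urls
    annotation_cols = [c for c in db.records.columns if c not in db.key_columns]
    merged[annotation_cols] = merged[annotation_cols].fillna("")
    return merged
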