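"""Deterministic synthetic-cohort generator.

Emulates a TMT-style log2 intensity matrix with a binary tumor/non-tumor
phenotype: per-feature baselines on a reporter-intensity-like scale, a
planted group shift on a fraction of features (half up, half down),
Gaussian residual noise, optional missingness, QC replicate samples that
are noisy copies of one base sample, and (optionally) glycoform-style
feature names.  Every draw flows from one seed, so identical specs yield
bit-identical cohorts.  Companion helpers emit toy GMT collections and
annotation databases in the exact dialects the readers accept, so the full
pipeline is testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_data import (
    CATEGORICAL,
    NUMERICAL,
    AnnotationTable,
    ExpressionMatrix,
    GlycoformID,
    PhenotypeTable,
    format_glycoform,
)
from .enrichment import GeneSetCollection

__all__ = [
    "FixtureSpec",
    "generate_cohort",
    "generate_toy_gmt",
    "generate_annotation_db",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GLYCAN_CODES = ("N", "H", "F", "S")

#: log2 baseline range mimicking reporter-intensity magnitudes (cosmetic).
BASELINE_RANGE = (18.0, 30.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe a 20-vs-20 comparison over 1000 features with 10%
    planted differential features at |log2FC| = 1 and residual sd 0.25 on
    the log2 scale, no missingness, and 3 QC replicates.
    """

    n_per_group: int = 20
    n_features: int = 1000
    frac_de: float = 0.10
    effect_log2fc: float = 1.0
    noise_sd: float = 0.25
    missing_rate: float = 0.0
    n_qc_replicates: int = 3
    glyco_mode: bool = False
    missing_mechanism: str = "mcar"  # or "censored" (left-censored, intensity-dependent)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must be in [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        if self.n_features < 1:
            raise ValueError("need >= 1 feature")
        if self.missing_mechanism not in ("mcar", "censored"):
            raise ValueError("missing_mechanism must be 'mcar' or 'censored'")


def _random_glycoform(rng: np.random.Generator, gene: str) -> str:
    peptide = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(8, 13)))
    start = int(rng.integers(1, 1000))
    position = start + int(rng.integers(0, len(peptide)))
    n_tokens = int(rng.integers(1, 4))
    codes = rng.choice(GLYCAN_CODES, size=n_tokens, replace=False)
    glycan = "".join(f"{c}{int(rng.integers(1, 10))}" for c in codes)
    return format_glycoform(
        GlycoformID(gene, start, peptide, 1, position, glycan)
    )


def _feature_names(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    genes = [f"GENE{i:04d}" for i in range(spec.n_features)]
    if not spec.glyco_mode:
        return genes
    return [_random_glycoform(rng, g) for g in genes]


def generate_cohort(
    spec: FixtureSpec,
) -> tuple[ExpressionMatrix, PhenotypeTable, pd.DataFrame]:
    """Generate (expression matrix, phenotype table, ground truth).

    log2 value = baseline(feature) + tumor_indicator * effect * direction
    + Normal(0, noise_sd).  Planted features split evenly between up and
    down directions and are recorded in the ground-truth table.  QC
    replicates copy the first tumor sample's realized profile plus fresh
    noise and carry missing phenotype values.  Missingness is injected
    completely at random (or left-censored in "censored" mode).
    """
    rng = np.random.default_rng(spec.seed)
    features = _feature_names(spec, rng)

    n_de = int(round(spec.frac_de * spec.n_features))
    de_idx = rng.choice(spec.n_features, size=n_de, replace=False)
    directions = np.zeros(spec.n_features)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    directions[de_idx] = signs

    baselines = rng.uniform(*BASELINE_RANGE, size=spec.n_features)
    tumor_ids = [f"T{i + 1:03d}" for i in range(spec.n_per_group)]
    normal_ids = [f"N{i + 1:03d}" for i in range(spec.n_per_group)]
    qc_ids = [f"QC{i + 1:02d}" for i in range(spec.n_qc_replicates)]

    n_main = 2 * spec.n_per_group
    is_tumor = np.repeat([1.0, 0.0], spec.n_per_group)
    signal = baselines[None, :] + is_tumor[:, None] * spec.effect_log2fc * directions[None, :]
    values = signal + rng.normal(0.0, spec.noise_sd, size=(n_main, spec.n_features))

    blocks = [values]
    if spec.n_qc_replicates > 0:
        base = values[0]  # first tumor sample's realized profile
        qc = base[None, :] + rng.normal(
            0.0, spec.noise_sd, size=(spec.n_qc_replicates, spec.n_features)
        )
        blocks.append(qc)
    grid = np.vstack(blocks)
    sample_ids = tumor_ids + normal_ids + qc_ids

    if spec.missing_rate > 0:
        if spec.missing_mechanism == "mcar":
            mask = rng.random(grid.shape) < spec.missing_rate
        else:
            # left-censored: drop probability decreases linearly with the
            # within-matrix intensity quantile; overall rate ~ missing_rate
            flat = grid.ravel()
            quantile = np.argsort(np.argsort(flat)) / (flat.size - 1)
            prob = (2.0 * spec.missing_rate * (1.0 - quantile)).reshape(grid.shape)
            mask = rng.random(grid.shape) < np.clip(prob, 0, 1)
        grid = np.where(mask, np.nan, grid)

    matrix = ExpressionMatrix(
        pd.DataFrame(grid, index=sample_ids, columns=features), log2_transformed=True
    )

    status = ["Tumor"] * spec.n_per_group + ["Non-Tumor"] * spec.n_per_group + [np.nan] * spec.n_qc_replicates
    grade_main = np.where(
        is_tumor == 1.0,
        2.0 + rng.integers(0, 2, size=n_main),
        1.0 + rng.integers(0, 2, size=n_main),
    )
    grade = list(grade_main) + [np.nan] * spec.n_qc_replicates
    phenotypes = PhenotypeTable(
        pd.DataFrame(
            {"Pathological_Status": status, "Grade": grade}, index=sample_ids
        ),
        kinds={"Pathological_Status": CATEGORICAL, "Grade": NUMERICAL},
    )

    truth = pd.DataFrame({
        "feature": features,
        "is_de": directions != 0,
        "direction": np.where(directions > 0, "up", np.where(directions < 0, "down", "")),
        "log2_fc": spec.effect_log2fc * directions,
    })
    return matrix, phenotypes, truth


def generate_toy_gmt(
    genes: list[str],
    n_sets: int,
    planted_set: set[str],
    seed: int,
    set_size: int = 20,
    n_decoys: int = 5,
    collection_name: str = "toy",
) -> GeneSetCollection:
    """Toy gene-set collection: one set holding the planted genes plus a few
    random decoys, the rest random draws from the gene universe."""
    planted_set = set(planted_set)
    stray = planted_set - set(genes)
    if stray:
        raise ValueError(f"planted genes outside the universe: {sorted(stray)[:5]}")
    rng = np.random.default_rng(seed)
    universe = sorted(genes)
    non_planted = sorted(set(universe) - planted_set)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    decoys = rng.choice(non_planted, size=min(n_decoys, len(non_planted)), replace=False)
    sets["PLANTED_SET"] = frozenset(planted_set | set(decoys))
    descriptions["PLANTED_SET"] = "synthetic planted pathway"
    for i in range(1, n_sets):
        members = rng.choice(universe, size=min(set_size, len(universe)), replace=False)
        sets[f"RANDOM_SET_{i:03d}"] = frozenset(members)
        descriptions[f"RANDOM_SET_{i:03d}"] = "synthetic random set"
    return GeneSetCollection(
        name=collection_name, sets=sets, descriptions=descriptions, source="synthetic"
    )


def generate_annotation_db(
    genes: list[str],
    url_template: str = "https://example.org/gene/{gene}",
) -> AnnotationTable:
    """Synthetic stand-in annotation database keyed on gene symbol."""
    records = pd.DataFrame({
        "gene": list(genes),
        "description": [f"synthetic annotation for {g}" for g in genes],
    })
    return AnnotationTable(records, ["gene"], url_template, name="synthetic")
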