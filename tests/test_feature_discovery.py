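"""Differential expression, BH adjustment, PCA contribution score, clustering."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from phenolink.core_data import CATEGORICAL, ExpressionMatrix, PhenotypeTable
from phenolink.feature_discovery import (
    DEConfig,
    benjamini_hochberg,
    cluster_features,
    differential_expression,
    pca_contribution,
)


def em(rows, features=None):
    rows = np.asarray(rows, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        rows,
        index=[f"S{i}" for i in range(rows.shape[0])],
        columns=features or [f"F{j}" for j in range(rows.shape[1])],
    ))


def two_group_table(n1, n2):
    ids = [f"S{i}" for i in range(n1 + n2)]
    status = ["Tumor"] * n1 + ["Non-Tumor"] * n2
    return PhenotypeTable(
        pd.DataFrame({"Pathological_Status": status}, index=ids),
        {"Pathological_Status": CATEGORICAL},
    )


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])

    def test_bounds_and_order_preservation(self):
        rng = np.random.default_rng(0)
        p = rng.random(40)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            p = rng.random(rng.integers(1, 50))
            ours = benjamini_hochberg(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(ours - theirs)) < 1e-12

    def test_nan_passthrough_shrinks_family(self):
        adj = benjamini_hochberg([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        expected = multipletests([0.01, 0.04], method="fdr_bh")[1]
        assert adj[[0, 2]] == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestDifferentialExpression:
    def test_planted_feature_called_up(self):
        rng = np.random.default_rng(7)
        g1 = rng.normal(2.0, 0.1, size=20)
        g2 = rng.normal(0.0, 0.1, size=20)
        noise = rng.normal(0.0, 0.1, size=(40, 4))
        rows = np.column_stack([np.concatenate([g1, g2]), *noise.T[:4]])
        res = differential_expression(em(rows), two_group_table(20, 20), DEConfig())
        row = res.table.set_index("feature").loc["F0"]
        assert row["direction"] == "up"
        assert row["log2_fc"] == pytest.approx(2.0, abs=0.15)
        assert row["fold_change"] == pytest.approx(4.0, rel=0.15)
        assert row["adj_p"] < 0.01

    def test_identical_groups_are_ns(self):
        rows = np.tile(np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])[:, None], (1, 3))
        res = differential_expression(em(rows), two_group_table(3, 3), DEConfig())
        assert (res.table["log2_fc"] == 0).all()
        assert (res.table["direction"] == "ns").all()

    def test_ranksum_exact_small_groups(self):
        # {1,2,3} vs {4,5,6}: most extreme of C(6,3)=20 assignments -> p = 2/20
        rows = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        cfg = DEConfig(test="wilcoxon_ranksum")
        res = differential_expression(em(rows), two_group_table(3, 3), cfg)
        assert res.table.loc[0, "raw_p"] == pytest.approx(0.1)

    def test_fold_change_consistency_invariant(self, default_cohort):
        m, p, _ = default_cohort
        res = differential_expression(m, p, DEConfig())
        t = res.table.dropna(subset=["log2_fc"])
        assert np.allclose(t["fold_change"], 2.0 ** t["log2_fc"])

    def test_untested_sparse_feature_reported_not_dropped(self):
        rows = np.array([[1.0], [np.nan], [np.nan], [2.0], [3.0], [4.0]])
        res = differential_expression(em(rows), two_group_table(3, 3), DEConfig())
        assert len(res.table) == 1
        assert not res.table.loc[0, "tested"]
        assert res.table.loc[0, "direction"] == "ns"

    def test_unknown_group_level_is_hard_error(self):
        cfg = DEConfig(group1="Metastatic")
        with pytest.raises(ValueError, match="Metastatic"):
            differential_expression(em([[1.0]] * 6), two_group_table(3, 3), cfg)

    def test_paired_test_with_orphan_pairs_errors(self):
        ids = [f"S{i}" for i in range(5)]
        p = PhenotypeTable(
            pd.DataFrame({
                "Pathological_Status": ["Tumor", "Tumor", "Tumor", "Non-Tumor", "Non-Tumor"],
                "Patient": ["p1", "p2", "p3", "p1", "p2"],
            }, index=ids),
            {"Pathological_Status": CATEGORICAL, "Patient": CATEGORICAL},
        )
        cfg = DEConfig(test="paired_t", paired_by="Patient")
        with pytest.raises(ValueError, match="p3"):
            differential_expression(em([[1.0]] * 5), p, cfg)

    def test_paired_t_detects_within_pair_shift(self):
        rng = np.random.default_rng(2)
        n = 12
        patient_effect = rng.normal(0, 5.0, size=n)
        tumor = patient_effect + 1.0 + rng.normal(0, 0.1, size=n)
        normal = patient_effect + rng.normal(0, 0.1, size=n)
        rows = np.concatenate([tumor, normal])[:, None]
        ids = [f"S{i}" for i in range(2 * n)]
        p = PhenotypeTable(
            pd.DataFrame({
                "Pathological_Status": ["Tumor"] * n + ["Non-Tumor"] * n,
                "Patient": [f"p{i}" for i in range(n)] * 2,
            }, index=ids),
            {"Pathological_Status": CATEGORICAL, "Patient": CATEGORICAL},
        )
        unpaired = differential_expression(
            ExpressionMatrix(pd.DataFrame(rows, index=ids, columns=["F0"])),
            p, DEConfig(test="student_t", adj_p_threshold=0.05))
        paired = differential_expression(
            ExpressionMatrix(pd.DataFrame(rows, index=ids, columns=["F0"])),
            p, DEConfig(test="paired_t", paired_by="Patient", adj_p_threshold=0.05))
        # pairing removes the large patient effect, so it is far more sensitive
        assert paired.table.loc[0, "raw_p"] < unpaired.table.loc[0, "raw_p"]
        assert paired.table.loc[0, "raw_p"] < 1e-6


class TestPCAContribution:
    def test_single_component_loading_split(self):
        # samples lie along direction (0.6, -0.2): S = (0.75, 0.25)
        t = np.array([-1.0, 0.0, 1.0, 2.0])
        rows = np.column_stack([0.6 * t, -0.2 * t])
        res = pca_contribution(em(rows), n_components=1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert res.contribution["F0"] == pytest.approx(0.75)
        assert res.contribution["F1"] == pytest.approx(0.25)

    def test_two_correlated_features_split_evenly(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        rows = np.column_stack([t, t])
        res = pca_contribution(em(rows), n_components=2)
        assert res.contribution["F0"] == pytest.approx(0.5, abs=1e-12)
        assert res.contribution["F1"] == pytest.approx(0.5, abs=1e-12)

    def test_conservation_identity_random(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            rows = rng.normal(size=(rng.integers(4, 12), rng.integers(3, 20)))
            res = pca_contribution(em(rows), n_components=5)
            assert res.contribution.sum() == pytest.approx(
                res.explained_variance_ratio.sum(), abs=1e-9
            )

    def test_component_clipping_warns(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="clipped"):
            res = pca_contribution(em(rng.normal(size=(3, 5))), n_components=10)
        assert len(res.explained_variance_ratio) == 2

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca_contribution(em(np.ones((4, 3))))

    def test_missing_values_rejected(self):
        rows = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            pca_contribution(em(rows))

    def test_top_k_and_per_component_lists(self):
        rng = np.random.default_rng(8)
        res = pca_contribution(em(rng.normal(size=(10, 30))), n_components=3, top_k=5)
        assert len(res.top_features) == 5
        assert list(res.contribution.index[:5]) == res.top_features
        assert all(len(v) == 10 for v in res.top_per_component.values())
        assert (np.diff(res.contribution.to_numpy()) <= 1e-15).all()


class TestClustering:
    def test_negated_blocks_separate(self):
        rng = np.random.default_rng(9)
        pattern = rng.normal(size=8)
        rows = np.column_stack(
            [pattern + rng.normal(0, 0.01, 8) for _ in range(4)]
            + [-pattern + rng.normal(0, 0.01, 8) for _ in range(4)]
        )
        res = cluster_features(em(rows), k=2)
        labels = res.assignments
        assert labels.iloc[:4].nunique() == 1
        assert labels.iloc[4:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[4]

    def test_k_equals_feature_count(self):
        rng = np.random.default_rng(10)
        res = cluster_features(em(rng.normal(size=(5, 6))), k=6)
        assert res.assignments.nunique() == 6

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(11)
        rows = rng.normal(size=(8, 12))
        m1 = em(rows)
        perm = rng.permutation(12)
        m2 = ExpressionMatrix(m1.data.iloc[:, perm])
        a1 = cluster_features(m1, k=3).assignments
        a2 = cluster_features(m2, k=3).assignments
        # same partition up to label permutation
        for f1 in m1.feature_ids:
            for f2 in m1.feature_ids:
                assert (a1[f1] == a1[f2]) == (a2[f1] == a2[f2])

    def test_constant_feature_named_in_error(self):
        rows = np.column_stack([np.ones(4), np.arange(4.0)])
        with pytest.raises(ValueError, match="F0"):
            cluster_features(em(rows), k=2)

    def test_invalid_k_rejected(self):
        rng = np.random.default_rng(12)
        m = em(rng.normal(size=(4, 3)))
        for k in (0, 4):
            with pytest.raises(ValueError):
                cluster_features(m, k=k)


def test_de_config_validation():
    with pytest.raises(ValueError):
        DEConfig(test="anova")
    with pytest.raises(ValueError):
        DEConfig(fc_threshold=1.0)
    with pytest.raises(ValueError):
        DEConfig(test="paired_t")  # paired without paired_by
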