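"""RLR training, ROC evaluation, AUC statistics, FDR, bootstrap."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from eegmarkers.classify import (auc_to_z, bca_auc_ci, compare_aucs, evaluate,
                                 fdr_bh, fit_rlr, roc_metrics,
                                 univariate_models, venn_intersection)
from eegmarkers.selection import SelectionResult, zscore_pooled

from test_selection import make_table


def _pca_selection(z, cohort="AS_like"):
    from eegmarkers.selection import pca_select
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pca_select(z, cohort)


class TestFitRLR:
    def test_separable_data_reaches_perfect_training_auc(self):
        z = zscore_pooled(make_table(
            10, seed=1, effects={"LZ": 3.0, "CTW": 3.0, "mMSE": 3.0},
        ))
        sel = _pca_selection(z)
        model = fit_rlr(z, sel, "scEntropy", seed=0)
        assert evaluate(model, z).auc == 1.0

    def test_null_labels_give_chance_cv_auc(self):
        z = zscore_pooled(make_table(20, seed=2))
        sel = _pca_selection(z)
        model = fit_rlr(z, sel, "scEntropy", seed=3)
        assert 0.3 <= model.cv_auc <= 0.7

    def test_lambda_choice_is_seed_deterministic(self):
        z = zscore_pooled(make_table(8, seed=3, effects={"LZ": 1.0}))
        sel = _pca_selection(z)
        m1 = fit_rlr(z, sel, "scEntropy", seed=5)
        m2 = fit_rlr(z, sel, "scEntropy", seed=5)
        assert m1.lambda_ == m2.lambda_
        np.testing.assert_array_equal(m1.coef, m2.coef)

    def test_single_class_rejected(self):
        z = zscore_pooled(make_table(6, seed=4))
        sel = _pca_selection(z)
        with pytest.raises(ValueError):
            fit_rlr(z[z["state"] == "wake"], sel, "scEntropy")

    def test_grouped_folds_never_split_participants(self):
        from eegmarkers.classify import _grouped_folds
        participants = np.repeat([f"p{i}" for i in range(12)], 2)
        folds = _grouped_folds(participants, 10, seed=1)
        for fold in folds:
            # both rows of every participant in the fold are present
            members = participants[fold]
            vals, counts = np.unique(members, return_counts=True)
            assert (counts == 2).all()


class TestEvaluate:
    def test_perfect_and_inverted_scores(self):
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        scores = np.r_[np.ones(10), np.zeros(10)]
        res = roc_metrics(y, scores)
        assert res.auc == 1.0
        assert res.accuracy == res.precision == res.recall == 1.0
        assert res.specificity == 1.0
        assert roc_metrics(y, -scores).auc == 0.0

    def test_random_scores_near_chance(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.ones(100), np.zeros(100)].astype(int)
        res = roc_metrics(y, rng.standard_normal(200))
        assert 0.4 <= res.auc <= 0.6


class TestAUCZ:
    def test_chance_maps_to_zero(self):
        out = auc_to_z(0.5, 10)
        assert out["z"] == 0.0
        assert out["p_one_tailed"] == pytest.approx(0.5)

    def test_printed_formula_arithmetic(self):
        out = auc_to_z(1.0, 5)
        assert out["U"] == 25
        assert out["z"] == pytest.approx(12.5 / math.sqrt(650 / 12.0),
                                         abs=1e-9)
        assert out["z"] == pytest.approx(1.6984, abs=1e-4)

    def test_classical_variance_agrees_with_enumeration(self):
        """At N = 6 the normal approximation with the classical
        Mann-Whitney variance stays within a factor of 2 of the exact
        permutation tail for AUC >= 0.8."""
        N = 6
        counts: dict[int, int] = {}
        for wset in combinations(range(2 * N), N):
            w = set(wset)
            U = sum(1 for i in wset for j in range(2 * N)
                    if j not in w and i > j)
            counts[U] = counts.get(U, 0) + 1
        total = sum(counts.values())
        for auc in (0.8, 0.9, 1.0):
            exact = sum(v for k, v in counts.items()
                        if k >= auc * N * N) / total
            approx = auc_to_z(auc, N, variance="classical")["p_one_tailed"]
            assert 0.5 <= approx / exact <= 2.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            auc_to_z(0.9, 1)


class TestCompareAUCs:
    def test_equal_aucs_give_zero(self):
        cmp = compare_aucs(0.8, 20, 0.8, 20)
        assert cmp.z_diff == 0.0
        assert cmp.p_two_tailed == pytest.approx(1.0)

    def test_z_difference_scaling(self):
        # z' times its pooled SE reconstructs z1 - z2
        cmp = compare_aucs(0.9, 39, 0.6, 39)
        z1 = auc_to_z(0.9, 39)["z"]
        z2 = auc_to_z(0.6, 39)["z"]
        se = math.sqrt(1 / 36 + 1 / 36)
        assert cmp.z_diff == pytest.approx((z1 - z2) / se, abs=1e-12)
        # and the printed worked arithmetic: (2 - 0)/sqrt(2/36) = 8.485...
        assert (2.0 - 0.0) / se == pytest.approx(8.485, abs=1e-3)

    def test_antisymmetry(self):
        a = compare_aucs(0.9, 20, 0.7, 20)
        b = compare_aucs(0.7, 20, 0.9, 20)
        assert a.z_diff == pytest.approx(-b.z_diff)

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            compare_aucs(0.9, 3, 0.8, 3)


class TestFdrBH:
    def test_single_p_unchanged(self):
        adj, rej = fdr_bh(np.array([0.03]))
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_equal_ps_stay_equal(self):
        adj, _ = fdr_bh(np.full(7, 0.02))
        np.testing.assert_allclose(adj, 0.02)

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests
        p = np.random.default_rng(6).random(20)
        adj, rej = fdr_bh(p, q=0.05)
        rej_ref, adj_ref, _, _ = multipletests(p, alpha=0.05,
                                               method="fdr_bh")
        np.testing.assert_allclose(adj, adj_ref, atol=1e-12)
        np.testing.assert_array_equal(rej, rej_ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.2, 1.4]))


class TestBootstrap:
    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        y = np.r_[np.ones(12), np.zeros(12)].astype(int)
        scores = rng.standard_normal(24) + y
        parts = np.r_[np.arange(12), np.arange(12)]
        a = bca_auc_ci(y, scores, parts, n_boot=300, seed=9)
        b = bca_auc_ci(y, scores, parts, n_boot=300, seed=9)
        assert a["ci"] == b["ci"]

    def test_saturated_auc_has_unit_upper_bound(self):
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        scores = y.astype(float)
        res = bca_auc_ci(y, scores, np.arange(20), n_boot=400, seed=1)
        assert res["ci"] == (1.0, 1.0)

    def test_paired_rows_move_together(self):
        # degenerate per-participant labels: if participants were split,
        # single-class resamples would occur constantly; paired resampling
        # never needs a redraw
        y = np.tile([1, 0], 10)
        scores = np.random.default_rng(8).standard_normal(20) + y
        parts = np.repeat(np.arange(10), 2)
        res = bca_auc_ci(y, scores, parts, n_boot=300, seed=2)
        assert res["n_redraws"] == 0


class TestUnivariate:
    def test_indicator_feature_is_perfect_everywhere(self):
        table = make_table(8, cohorts=("AS_like", "NT_like"), seed=9)
        table["LZ"] = (table["state"] == "wake").astype(float)
        out = univariate_models(zscore_pooled(table), "AS_like",
                                features=["LZ", "CTW"])
        lz = out[out["feature"] == "LZ"]
        assert (lz["auc"] == 1.0).all()
        ctw = out[out["feature"] == "CTW"]
        assert (ctw["auc"] - 0.5).abs().max() < 0.35

    def test_venn_intersection_set_arithmetic(self):
        df = pd.DataFrame([
            {"feature": "A", "cohort": "c1", "auc": 0.95},
            {"feature": "A", "cohort": "c2", "auc": 0.92},
            {"feature": "B", "cohort": "c1", "auc": 0.95},
            {"feature": "B", "cohort": "c2", "auc": 0.60},
        ])
        venn = venn_intersection(df, threshold=0.9)
        assert venn["all"] == {"A"}
        assert venn["c1"] == {"A", "B"}
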