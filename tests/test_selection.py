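"""Aggregation, z-scoring, and the two feature-selection paths."""

import numpy as np
import pandas as pd
import pytest

from eegmarkers.features import FEATURE_CATEGORIES
from eegmarkers.selection import (aggregate, length_robustness, lmm_select,
                                  pca_select, zscore_pooled)


def _tidy_row(rec_id, pid, cohort, state, feature, unit, value):
    return {
        "recording_id": rec_id, "participant_id": pid, "cohort": cohort,
        "state": state, "feature": feature,
        "category": FEATURE_CATEGORIES[feature], "unit": unit,
        "value": value, "usable_length_s": 60.0,
    }


def make_table(n_participants=10, cohorts=("AS_like",), seed=0,
               effects=None) -> pd.DataFrame:
    """Wide feature table with controllable per-feature state effects.

    ``effects`` maps feature name -> additive wake-vs-sleep offset; all
    features get unit-variance participant and residual noise.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    feats = list(FEATURE_CATEGORIES)
    for cohort in cohorts:
        for p in range(n_participants):
            pid = f"{cohort}_p{p}"
            intercepts = {f: rng.standard_normal() for f in feats}
            for state in ("wake", "nrem"):
                row = {
                    "recording_id": f"{pid}_{state}",
                    "participant_id": pid, "cohort": cohort, "state": state,
                    "usable_length_s": 60.0 + 10 * rng.random(),
                }
                for f in feats:
                    v = intercepts[f] + 0.3 * rng.standard_normal()
                    if state == "wake":
                        v += effects.get(f, 0.0)
                    row[f] = v
                rows.append(row)
    return pd.DataFrame(rows)


class TestAggregate:
    def test_identical_channel_values_average_to_value(self):
        rows = [_tidy_row("r1", "p1", "AS_like", "wake", "LZ", ch, 0.7)
                for ch in ("Cz", "Pz", "Fz")]
        rows.append(_tidy_row("r1", "p1", "AS_like", "wake", "SRwSMI8",
                              "SR", 0.1))
        wide = aggregate(pd.DataFrame(rows))
        assert wide.loc[0, "LZ"] == pytest.approx(0.7)
        assert not wide.loc[0, "partial_channels"]

    def test_missing_channel_sets_flag(self):
        rows = [_tidy_row("r1", "p1", "AS_like", "wake", "LZ", ch, 0.7)
                for ch in ("Cz", "Pz")]
        rows += [_tidy_row("r2", "p2", "AS_like", "wake", "LZ", ch, 0.5)
                 for ch in ("Cz",)]
        wide = aggregate(pd.DataFrame(rows))
        flags = wide.set_index("recording_id")["partial_channels"]
        assert not flags["r1"] and flags["r2"]


class TestZscore:
    def test_two_value_column(self):
        table = make_table(1, seed=1)
        table = table.iloc[:2].copy()
        table["LZ"] = [0.0, 2.0]
        z = zscore_pooled(table)
        np.testing.assert_allclose(
            z["LZ"].to_numpy(), [-0.7071, 0.7071], atol=1e-4
        )

    def test_columns_standardized(self):
        z = zscore_pooled(make_table(8, seed=2))
        for col in ("LZ", "PermEn32", "SRdwPLI_theta"):
            assert z[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert z[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_column_names_offender(self):
        table = make_table(4, seed=3)
        table["CTW"] = 1.0
        with pytest.raises(ValueError, match="CTW"):
            zscore_pooled(table)


class TestLmmSelect:
    def test_state_indicator_feature_has_beta_two(self):
        rng = np.random.default_rng(4)
        table = make_table(20, seed=4)
        indicator = (table["state"] == "nrem").astype(float)
        table["LZ"] = indicator + 0.01 * rng.standard_normal(len(table))
        z = zscore_pooled(table)
        res = lmm_select(z, "AS_like")
        assert res.betas["LZ"] == pytest.approx(2.0, abs=0.1)
        assert "LZ" in res.selected["scEntropy"]

    def test_null_features_rarely_selected(self):
        table = make_table(40, seed=5)
        z = zscore_pooled(table)
        res = lmm_select(z, "AS_like")
        n_selected = sum(len(v) for v in res.selected.values())
        # 42 independent null features at ~2.6% selection probability
        assert n_selected <= 9

    def test_beta_exactly_at_threshold_not_selected(self):
        # an exact noiseless within-participant shift of 0.5 fits to
        # beta == 0.5, which the strict rule must NOT select
        table = make_table(10, seed=6)
        rng = np.random.default_rng(6)
        intercepts = {p: rng.standard_normal()
                      for p in table["participant_id"].unique()}
        table["LZ"] = [
            intercepts[p] + (0.5 if s == "nrem" else 0.0)
            for p, s in zip(table["participant_id"], table["state"])
        ]
        res = lmm_select(table, "AS_like")
        assert res.betas["LZ"] == pytest.approx(0.5, abs=1e-8)
        assert "LZ" not in res.selected["scEntropy"]

    def test_selection_ignores_validation_rows(self):
        z = zscore_pooled(make_table(
            8, cohorts=("AS_like", "NT_like"), seed=7,
            effects={"LZ": 1.0, "PermEn32": -1.0},
        ))
        full = lmm_select(z, "AS_like")
        train_only = lmm_select(z[z["cohort"] == "AS_like"], "AS_like")
        assert full.selected == train_only.selected
        for f in full.betas:
            assert full.betas[f] == pytest.approx(train_only.betas[f],
                                                  abs=1e-9)


class TestPcaSelect:
    def test_rank_one_contrast_needs_single_component(self):
        table = make_table(6, seed=8)
        z = zscore_pooled(table)
        # overwrite one category with an exactly rank-one contrast
        cols = [c for c in z.columns if FEATURE_CATEGORIES.get(c) == "scEntropy"]
        direction = np.linspace(1.0, 2.0, len(cols))
        for p, pid in enumerate(z["participant_id"].unique()):
            for state, s in (("wake", 0.5), ("nrem", -0.5)):
                sel = (z["participant_id"] == pid) & (z["state"] == state)
                z.loc[sel, cols] = (p + 1) * s * direction
        res = pca_select(z, "AS_like")
        assert res.k["scEntropy"] == 1
        assert res.eigenvalues["scEntropy"][0] == pytest.approx(1.0)

    def test_component_count_matches_reference_eigendecomposition(self):
        z = zscore_pooled(make_table(12, seed=9))
        res = pca_select(z, "AS_like", var_threshold=0.9)
        for category, cols in (
            ("fcSpectral", [c for c in z.columns
                            if FEATURE_CATEGORIES.get(c) == "fcSpectral"]),
        ):
            w = z[z["state"] == "wake"].set_index("participant_id")[cols]
            s = z[z["state"] == "nrem"].set_index("participant_id")[cols]
            D = (w - s.loc[w.index]).to_numpy()
            evals = np.linalg.svd(D, compute_uv=False) ** 2
            cum = np.cumsum(evals) / evals.sum()
            k_ref = int(np.searchsorted(cum, 0.9 - 1e-12) + 1)
            assert res.k[category] == k_ref

    def test_loadings_are_orthonormal(self):
        res = pca_select(zscore_pooled(make_table(10, seed=10)), "AS_like")
        for L in res.loadings.values():
            np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]),
                                       atol=1e-9)

    def test_selection_ignores_validation_rows(self):
        z = zscore_pooled(make_table(
            8, cohorts=("AS_like", "DUP_like"), seed=11,
            effects={"CTW": 0.8},
        ))
        full = pca_select(z, "AS_like")
        sub = pca_select(z[z["cohort"] == "AS_like"], "AS_like")
        for cat in full.loadings:
            np.testing.assert_allclose(full.loadings[cat],
                                       sub.loadings[cat], atol=1e-12)


class TestLengthRobustness:
    def test_length_dependent_feature_is_flagged(self):
        table = make_table(15, seed=12)
        table["LZ"] = (table["usable_length_s"]
                       + 0.01 * np.random.default_rng(0).standard_normal(
                           len(table)))
        out = length_robustness(table)
        assert len(out) == 42
        row = out.set_index("feature").loc["LZ"]
        assert row["significant"]

    def test_independent_features_mostly_clean(self):
        out = length_robustness(make_table(15, seed=13))
        assert out["significant"].sum() <= 4
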