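"""Channel averaging, pooled z-scoring, and feature selection.

Two complementary selection paths operate on the 42-column feature table
(one row per recording-state):

* a linear-mixed-model path: each z-scored feature is regressed on
  conscious state with participant random intercepts, and features with
  ``|beta| > 0.5`` (strict) are selected within each category;
* a principal-component path: PCA of the participant-level wake - sleep
  difference vectors per category, keeping the minimum number of
  components whose cumulative explained variance reaches 90%.

Both paths are fit on the training cohort only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CATEGORIES, FEATURE_CATEGORIES
from .records import NREM, WAKE

META_COLUMNS = ("recording_id", "participant_id", "cohort", "state",
                "usable_length_s")

#: state coding used throughout: wake = 0, NREM sleep = 1
STATE_CODE = {WAKE: 0.0, NREM: 1.0}


def aggregate(tidy: pd.DataFrame) -> pd.DataFrame:
    """Collapse tidy per-channel rows into the wide recording x feature table.

    SC features are averaged across available channels (a ``partial_sc``
    flag is set when channels are missing relative to the montage count of
    the recording's cohort); FC features are already class-averaged.
    """
    agg = (
        tidy.groupby(
            ["recording_id", "participant_id", "cohort", "state", "feature"],
            sort=False,
        )
        .agg(value=("value", "mean"), n_units=("value", "size"))
        .reset_index()
    )
    wide = agg.pivot_table(
        index=["recording_id", "participant_id", "cohort", "state"],
        columns="feature", values="value", sort=False,
    ).reset_index()
    wide.columns.name = None
    order = [f for f in FEATURE_CATEGORIES if f in wide.columns]
    lengths = tidy.groupby("recording_id")["usable_length_s"].first()
    wide["usable_length_s"] = wide["recording_id"].map(lengths)
    # flag recordings whose single-channel means cover fewer channels than
    # the table-wide maximum for that feature
    units = agg.pivot_table(index="recording_id", columns="feature",
                            values="n_units", sort=False)
    partial = (units < units.max(axis=0)).any(axis=1)
    wide["partial_channels"] = wide["recording_id"].map(partial).fillna(False)
    return wide[list(wide.columns[:4]) + order
                + ["usable_length_s", "partial_channels"]]


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c in FEATURE_CATEGORIES]


def zscore_pooled(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize every feature column over all rows (all cohorts, both
    states pooled), with the n-1 SD convention."""
    if len(table) < 2:
        raise ValueError("z-scoring requires at least 2 rows")
    out = table.copy()
    for col in feature_columns(table):
        x = out[col].to_numpy(dtype=float)
        sd = np.nanstd(x, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance feature column: {col}")
        out[col] = (x - np.nanmean(x)) / sd
    return out


@dataclass
class SelectionResult:
    """Outcome of either selection path, restricted to one training cohort."""

    method: str                                  # "LMM" | "PCA"
    selected: dict[str, list[str]] = field(default_factory=dict)
    betas: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)
    loadings: dict[str, np.ndarray] = field(default_factory=dict)
    eigenvalues: dict[str, np.ndarray] = field(default_factory=dict)
    feature_order: dict[str, list[str]] = field(default_factory=dict)
    k: dict[str, int] = field(default_factory=dict)

    def predictors(self, table: pd.DataFrame, category: str) -> np.ndarray:
        """Design matrix of the selected features / projected PCs."""
        if self.method == "LMM":
            cols = self.selected.get(category, [])
            if not cols:
                raise ValueError(f"no features selected in {category}")
            return table[cols].to_numpy(dtype=float)
        order = self.feature_order[category]
        X = table[order].to_numpy(dtype=float)
        return X @ self.loadings[category]

    def to_json_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": self.selected,
            "betas": self.betas,
            "flags": self.flags,
            "k": self.k,
            "eigenvalues": {c: v.tolist() for c, v in self.eigenvalues.items()},
            "loadings": {c: v.tolist() for c, v in self.loadings.items()},
            "feature_order": self.feature_order,
        }


def _lmm_beta(y: np.ndarray, state: np.ndarray, groups: np.ndarray
              ) -> tuple[float, float, str]:
    """REML mixed-model coefficient of state with participant random
    intercepts; falls back to the paired-difference mean on singular fits.

    Returns (beta, p_value, flag).
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    ok = np.isfinite(y)
    y, state, groups = y[ok], state[ok], groups[ok]
    X = sm.add_constant(state)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", RuntimeWarning)
            model = sm.MixedLM(y, X, groups=groups)
            fit = model.fit(reml=True)
        beta = float(fit.params.iloc[1] if hasattr(fit.params, "iloc")
                     else fit.params[1])
        p = float(fit.pvalues.iloc[1] if hasattr(fit.pvalues, "iloc")
                  else fit.pvalues[1])
        if not np.isfinite(beta):
            raise ValueError("non-finite coefficient")
        return beta, p, ""
    except Exception:
        # paired-difference fallback (equals the fixed effect in the
        # balanced two-state design)
        df = pd.DataFrame({"y": y, "s": state, "g": groups})
        piv = df.pivot_table(index="g", columns="s", values="y")
        if piv.shape[1] == 2:
            diffs = (piv[1.0] - piv[0.0]).dropna()
            if len(diffs):
                from scipy import stats
                beta = float(diffs.mean())
                if len(diffs) > 1 and diffs.std(ddof=1) > 0:
                    p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
                else:
                    p = float("nan")
                return beta, p, "paired_fallback"
        return float("nan"), float("nan"), "failed"


def lmm_select(
    table: pd.DataFrame,
    training_cohort: str,
    threshold: float = 0.5,
) -> SelectionResult:
    """Mixed-model feature selection: ``|beta_state| > threshold`` (strict),
    fit on the training cohort's z-scored features."""
    train = table[table["cohort"] == training_cohort]
    if train.empty:
        raise ValueError(f"no rows for training cohort {training_cohort!r}")
    states = set(train["state"])
    if states != {WAKE, NREM}:
        raise ValueError("training cohort must contain both states")
    state = train["state"].map(STATE_CODE).to_numpy(dtype=float)
    groups = train["participant_id"].to_numpy()
    result = SelectionResult(method="LMM")
    for category in CATEGORIES:
        cols = [c for c in feature_columns(table)
                if FEATURE_CATEGORIES[c] == category]
        chosen = []
        for col in cols:
            beta, _, flag = _lmm_beta(
                train[col].to_numpy(dtype=float), state, groups
            )
            result.betas[col] = beta
            if flag:
                result.flags[col] = flag
            # strict inequality with a numerical guard so a coefficient
            # landing exactly on the threshold is not selected
            if np.isfinite(beta) and abs(beta) > threshold + 1e-9:
                chosen.append(col)
        result.selected[category] = chosen
    return result


def pca_select(
    table: pd.DataFrame,
    training_cohort: str,
    var_threshold: float = 0.90,
    expected_k: tuple[int, int] = (2, 5),
    center: bool = False,
) -> SelectionResult:
    """PCA of participant-level wake - sleep contrasts, per category.

    Loadings are eigenvectors of the second-moment matrix of the
    difference vectors; k is the smallest number of components reaching
    ``var_threshold`` cumulative explained contrast energy.  The stored
    loadings project any z-scored state-level feature vector onto the
    components.

    By default the difference vectors are *not* mean-centered: the leading
    component then captures the average wake - sleep contrast itself
    (plus its dominant interactions), which is the structure the
    downstream classifier needs.  With ``center=True`` the conventional
    covariance PCA of the contrasts is used instead; when the mean
    contrast is large relative to its between-participant variability the
    centered variant describes only participant idiosyncrasies and
    transfers poorly.
    """
    train = table[table["cohort"] == training_cohort]
    if train.empty:
        raise ValueError(f"no rows for training cohort {training_cohort!r}")
    result = SelectionResult(method="PCA")
    for category in CATEGORIES:
        cols = [c for c in feature_columns(table)
                if FEATURE_CATEGORIES[c] == category]
        piv_w = train[train["state"] == WAKE].set_index("participant_id")[cols]
        piv_s = train[train["state"] == NREM].set_index("participant_id")[cols]
        common = piv_w.index.intersection(piv_s.index)
        if len(common) < 2:
            raise ValueError(
                f"need wake and sleep rows for >= 2 participants in {category}"
            )
        diffs = (piv_w.loc[common].to_numpy(dtype=float)
                 - piv_s.loc[common].to_numpy(dtype=float))
        ok_cols = np.all(np.isfinite(diffs), axis=0)
        used = [c for c, o in zip(cols, ok_cols) if o]
        D = diffs[:, ok_cols]
        if center:
            D = D - D.mean(axis=0, keepdims=True)
        cov = D.T @ D / max(len(common) - 1, 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0, None)
        evecs = evecs[:, order]
        total = evals.sum()
        if total <= 0:
            raise ValueError(f"degenerate difference matrix in {category}")
        cum = np.cumsum(evals) / total
        k = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
        if k > len(used):
            k = len(used)
            result.flags[category] = "all_components"
        if not expected_k[0] <= k <= expected_k[1]:
            warnings.warn(
                f"{category}: {k} principal components needed "
                f"(expected {expected_k[0]}-{expected_k[1]})", stacklevel=2,
            )
        result.loadings[category] = evecs[:, :k]
        result.eigenvalues[category] = evals / total
        result.feature_order[category] = used
        result.k[category] = k
    return result


def length_robustness(
    table: pd.DataFrame, fdr_q: float = 0.05
) -> pd.DataFrame:
    """Per-feature mixed model with cohort, state and usable data length.

    Returns one row per feature with the LENGTH coefficient, its p-value
    and a Benjamini-Hochberg rejection flag at ``fdr_q``.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    from .classify import fdr_bh

    rows = []
    for col in feature_columns(table):
        df = pd.DataFrame({
            "y": table[col].to_numpy(dtype=float),
            "group": table["cohort"].astype("category"),
            "conscious": table["state"].map(STATE_CODE),
            "length": table["usable_length_s"].to_numpy(dtype=float),
            "participant": table["participant_id"],
        }).dropna()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                fit = smf.mixedlm(
                    "y ~ group + conscious + length", df, groups="participant"
                ).fit(reml=True)
            coef = float(fit.params["length"])
            p = float(fit.pvalues["length"])
            flag = ""
        except Exception:
            coef, p, flag = float("nan"), float("nan"), "failed"
        rows.append({"feature": col, "length_coef": coef, "p": p,
                     "flag": flag})
    out = pd.DataFrame(rows)
    pvals = out["p"].to_numpy(dtype=float)
    ok = np.isfinite(pvals)
    adj = np.full(len(out), np.nan)
    rej = np.zeros(len(out), dtype=bool)
    if ok.sum():
        adj_ok, rej_ok = fdr_bh(pvals[ok], fdr_q)
        adj[ok] = adj_ok
        rej[ok] = rej_ok
    out["p_fdr"] = adj
    out["significant"] = rej
    return out
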