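"""Regularized logistic regression, ROC evaluation, and AUC statistics.

The classifier is a regularized logistic regression (RLR) over the
selected features or principal components, with the regularization
strength chosen from a 100-point logarithmic grid by grouped k-fold
cross-validated deviance: a participant's wake and sleep rows always fall
on the same side of every partition.  Wakefulness is the positive class.

AUC inference follows the Mann-Whitney correspondence ``U = AUC * N^2``
for a balanced design with N participants per class, the normal
approximation ``z = (U - N^2/2) / sqrt(N^2 (N^2 + 1) / 12)``, and the
z-difference statistic ``z' = (z1 - z2) / sqrt(1/(N1-3) + 1/(N2-3))``.
Note the variance in the z formula differs from the classical
Mann-Whitney variance ``N^2 (2N + 1) / 12``; both are available and the
former is the default.  Confidence intervals for AUC and operating-point
metrics use a participant-paired bias-corrected and accelerated (BCa)
bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score, roc_curve

from .records import NREM, WAKE
from .selection import STATE_CODE, SelectionResult, feature_columns


@dataclass(frozen=True)
class RLRSpec:
    lambda_min: float = 4.4e-5
    lambda_max: float = 0.44
    n_lambda: int = 100
    cv_folds: int = 10
    penalty: str = "l1"        # "l1" (default) or "l2"

    @property
    def lambda_grid(self) -> np.ndarray:
        return np.logspace(
            math.log10(self.lambda_min), math.log10(self.lambda_max),
            self.n_lambda,
        )


@dataclass
class RLRModel:
    category: str
    selection: SelectionResult
    coef: np.ndarray
    intercept: float
    lambda_: float
    cv_deviance: np.ndarray            # per grid point
    cv_auc: float                      # out-of-fold AUC at the chosen lambda
    spec: RLRSpec

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        X = self.selection.predictors(table, self.category)
        return X @ self.coef + self.intercept


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    accuracy: float
    precision: float
    recall: float
    specificity: float
    threshold: float
    n_per_class: dict[str, int]
    ci: tuple[float, float] | None = None


@dataclass
class AUCComparison:
    auc1: float
    auc2: float
    z1: float
    z2: float
    z_diff: float
    p_two_tailed: float
    p_fdr: float | None = None


def _labels(table: pd.DataFrame) -> np.ndarray:
    """wake -> 1 (positive/conscious class), NREM -> 0."""
    return (table["state"] == WAKE).to_numpy(dtype=int)


def _grouped_folds(
    participants: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Row-index folds that never split a participant across folds."""
    uniq = np.unique(participants)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    folds: list[list[int]] = [[] for _ in range(min(n_folds, len(uniq)))]
    for slot, pi in enumerate(order):
        folds[slot % len(folds)].append(pi)
    out = []
    for f in folds:
        members = set(uniq[f])
        out.append(np.flatnonzero(
            np.fromiter((p in members for p in participants), dtype=bool)
        ))
    return out


def _sk_model(lam: float, n: int, penalty: str) -> LogisticRegression:
    # sklearn minimizes C * sum(loss) + penalty; per-observation lambda
    # translates to C = 1 / (lambda * n)
    return LogisticRegression(
        l1_ratio=1.0 if penalty == "l1" else 0.0,
        C=1.0 / (lam * n), solver="liblinear", max_iter=2000, tol=1e-7,
        random_state=0,
    )


def fit_rlr(
    train: pd.DataFrame,
    selection: SelectionResult,
    category: str,
    spec: RLRSpec = RLRSpec(),
    seed: int = 0,
) -> RLRModel:
    """Fit RLR on the training cohort rows for one feature category.

    The regularization parameter is chosen to minimize grouped-CV
    deviance over the lambda grid; the returned model is refit on the
    full training data at that lambda.
    """
    y = _labels(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = selection.predictors(train, category)
    participants = train["participant_id"].to_numpy()
    folds = _grouped_folds(participants, spec.cv_folds, seed)
    grid = spec.lambda_grid
    dev = np.zeros(len(grid))
    oof_scores = np.full((len(grid), len(y)), np.nan)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        if len(np.unique(y[train_idx])) < 2:
            continue
        for li, lam in enumerate(grid):
            clf = _sk_model(lam, len(train_idx), spec.penalty)
            clf.fit(X[train_idx], y[train_idx])
            p = clf.predict_proba(X[test_idx])[:, 1]
            dev[li] += log_loss(y[test_idx], p, labels=[0, 1]) * len(test_idx)
            oof_scores[li, test_idx] = clf.decision_function(X[test_idx])
    best = int(np.argmin(dev))
    lam = float(grid[best])
    with np.errstate(invalid="ignore"):
        row = oof_scores[best]
        ok = np.isfinite(row)
        cv_auc = (float(roc_auc_score(y[ok], row[ok]))
                  if ok.any() and len(np.unique(y[ok])) == 2 else float("nan"))
    final = _sk_model(lam, len(y), spec.penalty)
    final.fit(X, y)
    return RLRModel(
        category=category, selection=selection,
        coef=final.coef_.ravel().copy(), intercept=float(final.intercept_[0]),
        lambda_=lam, cv_deviance=dev, cv_auc=cv_auc, spec=spec,
    )


def roc_metrics(y: np.ndarray, scores: np.ndarray) -> ROCResult:
    """ROC curve, AUC and operating-point metrics at the Youden-J optimum."""
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation requires both classes")
    fpr, tpr, thresh = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    j = int(np.argmax(tpr - fpr))
    t = float(thresh[j])
    pred = (scores >= t).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return ROCResult(
        fpr=fpr, tpr=tpr, auc=auc,
        accuracy=(tp + tn) / len(y),
        precision=tp / (tp + fp) if tp + fp else float("nan"),
        recall=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        threshold=t,
        n_per_class={WAKE: int((y == 1).sum()), NREM: int((y == 0).sum())},
    )


def evaluate(model: RLRModel, table: pd.DataFrame) -> ROCResult:
    """Evaluate a trained model on a (training or validation) table."""
    return roc_metrics(_labels(table), model.scores(table))


# ---------------------------------------------------------------------------
# participant-paired BCa bootstrap
# ---------------------------------------------------------------------------

def _auc_fast(y: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), with midranks for tied scores."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    r = stats.rankdata(scores)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bca_auc_ci(
    y: np.ndarray,
    scores: np.ndarray,
    participants: np.ndarray,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    max_redraws: int = 100,
) -> dict:
    """BCa bootstrap CI for the AUC with the participant as resampling unit.

    All of a participant's rows (both states) enter or leave a resample
    together, respecting the repeated-measures structure.  Degenerate
    resamples containing a single class are redrawn (the count is
    reported).  Returns the CI, the resample histogram and diagnostics.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    participants = np.asarray(participants)
    uniq = np.unique(participants)
    if min(int((y == 1).sum()), int((y == 0).sum())) < 1:
        raise ValueError("need both classes")
    rows_by_p = {p: np.flatnonzero(participants == p) for p in uniq}
    theta = _auc_fast(y, scores)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n_redraws = 0
    for b in range(n_boot):
        for _ in range(max_redraws + 1):
            pick = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([rows_by_p[p] for p in pick])
            yb = y[idx]
            if 0 < yb.sum() < len(yb):
                break
            n_redraws += 1
        boot[b] = _auc_fast(yb, scores[idx])
    if np.allclose(boot, boot[0]):
        v = float(boot[0])
        return {"ci": (v, v), "boot": boot, "theta": theta,
                "n_redraws": n_redraws, "z0": 0.0, "accel": 0.0}
    # bias correction
    prop = np.mean(boot < theta)
    prop = min(max(prop, 1.0 / (n_boot + 1)), 1.0 - 1.0 / (n_boot + 1))
    z0 = stats.norm.ppf(prop)
    # acceleration from participant-level jackknife
    jack = np.empty(len(uniq))
    for i, p in enumerate(uniq):
        keep = participants != p
        yk = y[keep]
        if 0 < yk.sum() < len(yk):
            jack[i] = _auc_fast(yk, scores[keep])
        else:
            jack[i] = theta
    d = jack.mean() - jack
    denom = (d ** 2).sum() ** 1.5
    accel = float((d ** 3).sum() / (6.0 * denom)) if denom > 0 else 0.0
    out = []
    for a in (alpha / 2.0, 1.0 - alpha / 2.0):
        za = stats.norm.ppf(a)
        adj = stats.norm.cdf(z0 + (z0 + za) / (1.0 - accel * (z0 + za)))
        out.append(float(np.quantile(boot, min(max(adj, 0.0), 1.0))))
    return {"ci": (out[0], out[1]), "boot": boot, "theta": theta,
            "n_redraws": n_redraws, "z0": float(z0), "accel": accel}


def bootstrap_auc(
    model: RLRModel,
    table: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Participant-paired BCa bootstrap of a model's AUC on a table."""
    return bca_auc_ci(
        _labels(table), model.scores(table),
        table["participant_id"].to_numpy(), n_boot=n_boot, alpha=alpha,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# AUC -> z statistics
# ---------------------------------------------------------------------------

def auc_to_z(auc: float, N: int, variance: str = "printed") -> dict:
    """Map an AUC from a balanced N-vs-N design to a Mann-Whitney z-score.

    ``variance="printed"`` uses ``N^2 (N^2 + 1) / 12``;
    ``variance="classical"`` uses the standard null variance
    ``N^2 (2N + 1) / 12``.  The one-tailed p tests AUC > chance.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    U = auc * N * N
    if variance == "printed":
        var = N * N * (N * N + 1) / 12.0
    elif variance == "classical":
        var = N * N * (2 * N + 1) / 12.0
    else:
        raise ValueError("variance must be 'printed' or 'classical'")
    z = (U - N * N / 2.0) / math.sqrt(var)
    return {"U": U, "z": z, "p_one_tailed": float(stats.norm.sf(z))}


def compare_aucs(
    auc1: float, N1: int, auc2: float, N2: int,
    variance: str = "printed",
) -> AUCComparison:
    """Two-tailed comparison of two AUCs via the z-difference statistic."""
    if N1 <= 3 or N2 <= 3:
        raise ValueError("N must exceed 3 for the z-difference statistic")
    if N1 != N2:
        warnings.warn(
            "z-difference comparison is only a valid significance test "
            "for equal sample sizes", stacklevel=2,
        )
    z1 = auc_to_z(auc1, N1, variance)["z"]
    z2 = auc_to_z(auc2, N2, variance)["z"]
    zd = (z1 - z2) / math.sqrt(1.0 / (N1 - 3) + 1.0 / (N2 - 3))
    p = float(2.0 * stats.norm.sf(abs(zd)))
    return AUCComparison(auc1=auc1, auc2=auc2, z1=z1, z2=z2, z_diff=zd,
                         p_two_tailed=p)


def fdr_bh(p_values: np.ndarray, q: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg linear step-up procedure.

    Returns (adjusted p-values, rejection flags at level q).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(n)
    adj[order] = adj_sorted
    return adj, adj <= q


# ---------------------------------------------------------------------------
# univariate (unregularized) models
# ---------------------------------------------------------------------------

def univariate_models(
    table: pd.DataFrame,
    training_cohort: str,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Unregularized per-feature logistic models trained on one cohort and
    evaluated on every cohort.

    Returns a row per (feature, cohort) with AUC and operating-point
    metrics; perfect-separation fits are refit with a tiny ridge penalty
    and flagged.
    """
    feats = features or feature_columns(table)
    train = table[table["cohort"] == training_cohort]
    y_train = _labels(train)
    rows = []
    for feat in feats:
        x = train[feat].to_numpy(dtype=float)[:, None]
        ok = np.isfinite(x[:, 0])
        clf = LogisticRegression(l1_ratio=0.0, C=1e6, solver="lbfgs",
                                 max_iter=5000)
        clf.fit(x[ok], y_train[ok])
        flag = ""
        if np.abs(clf.coef_).max() > 1e3:
            clf = LogisticRegression(l1_ratio=0.0, C=1e2, solver="lbfgs",
                                     max_iter=5000)
            clf.fit(x[ok], y_train[ok])
            flag = "ridge_jitter"
        for cohort, sub in table.groupby("cohort"):
            xs = sub[feat].to_numpy(dtype=float)[:, None]
            oks = np.isfinite(xs[:, 0])
            if oks.sum() < 2 or len(np.unique(_labels(sub)[oks])) < 2:
                continue
            res = roc_metrics(_labels(sub)[oks],
                              clf.decision_function(xs[oks]))
            rows.append({
                "feature": feat, "cohort": cohort, "auc": res.auc,
                "accuracy": res.accuracy, "precision": res.precision,
                "recall": res.recall, "specificity": res.specificity,
                "flag": flag,
            })
    return pd.DataFrame(rows)


def venn_intersection(
    univariate: pd.DataFrame, threshold: float = 0.90
) -> dict[str, set[str]]:
    """Per-cohort sets of features with AUC >= threshold, plus their
    intersection under key ``"all"``."""
    sets = {
        cohort: set(sub.loc[sub["auc"] >= threshold, "feature"])
        for cohort, sub in univariate.groupby("cohort")
    }
    inter = set.intersection(*sets.values()) if sets else set()
    return {**sets, "all": inter}
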