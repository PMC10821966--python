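"""Model fitting and repeated-split evaluation harness.

The classifier is "ridge": an L2-penalized linear model with the penalty
strength chosen by stratified 10-fold cross-validation maximizing AUC.  The
default realization is L2-regularized logistic regression, which yields the
calibrated probabilities needed for threshold metrics and decision-curve
analysis; a ridge-regression-on-labels variant (probability via a logistic
link on the decision value) is available with ``mode="regression"``.

Evaluation follows the repeated-split design: 30 independent stratified 7:3
train/test splits, five metrics (AUC, accuracy, precision, recall, F1) per
cohort per iteration, aggregated as mean +/- STD with a 95% CI.  AUC
confidence intervals for a single score vector are available by the DeLong
analytic method or by 2000 stratified bootstrap resamples; models are
compared by a two-sided paired t-test on per-iteration AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV, RidgeClassifierCV
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "RidgeConfig",
    "FittedRidge",
    "EvalReport",
    "NetBenefitCurve",
    "METRICS",
    "fit_ridge",
    "evaluate",
    "repeated_evaluation",
    "auc_ci",
    "paired_model_test",
    "net_benefit_curve",
]

METRICS = ("AUC", "ACC", "Pre", "Re", "F1")


@dataclass(frozen=True)
class RidgeConfig:
    """Hyper-parameter search space for the ridge classifier."""

    alphas: tuple[float, ...] = tuple(np.logspace(-3, 3, 13))
    n_folds: int = 10
    mode: str = "logistic"  # or "regression"

    def __post_init__(self) -> None:
        if self.mode not in ("logistic", "regression"):
            raise ValueError("mode must be 'logistic' or 'regression'")


@dataclass
class FittedRidge:
    estimator: object
    mode: str

    def decision(self, X) -> np.ndarray:
        return np.asarray(self.estimator.decision_function(np.asarray(X, float)))

    def predict_proba(self, X) -> np.ndarray:
        """P(EF = 1); logistic link on the decision value in both modes."""
        return 1.0 / (1.0 + np.exp(-self.decision(X)))


def fit_ridge(
    train_features, labels, cfg: RidgeConfig | None = None, seed: int = 0
) -> FittedRidge:
    """Fit the L2-penalized classifier with CV-tuned penalty strength.

    Folds are capped at the minority-class count so small cohorts remain
    fittable; single-class training data is rejected.
    """
    cfg = cfg or RidgeConfig()
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    folds = int(min(cfg.n_folds, counts.min()))
    cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=seed)
    if cfg.mode == "logistic":
        est = LogisticRegressionCV(
            Cs=[1.0 / a for a in cfg.alphas],
            cv=cv,
            penalty="l2",
            scoring="roc_auc",
            solver="lbfgs",
            max_iter=2000,
        )
    else:
        est = RidgeClassifierCV(alphas=list(cfg.alphas), cv=cv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return FittedRidge(estimator=est, mode=cfg.mode)


def evaluate(model: FittedRidge, features, labels) -> dict[str, float]:
    """The five evaluation metrics on one cohort.

    AUC from the continuous score (tied scores get half credit); accuracy,
    precision, recall and F1 at probability threshold 0.5.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation cohort must contain both classes")
    prob = model.predict_proba(features)
    pred = (prob >= 0.5).astype(int)
    return {
        "AUC": float(roc_auc_score(y, prob)),
        "ACC": float(accuracy_score(y, pred)),
        "Pre": float(precision_score(y, pred, zero_division=0)),
        "Re": float(recall_score(y, pred, zero_division=0)),
        "F1": float(f1_score(y, pred, zero_division=0)),
    }


@dataclass
class EvalReport:
    """Per-iteration train/test metrics of one model, with aggregates."""

    model_tag: str
    records: pd.DataFrame  # columns: iteration, cohort, AUC..F1, n_features
    selected_features: list[str] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        """Mean, STD and 95% CI of each metric per cohort across iterations.

        The CI is the t-interval for the mean of the per-iteration values;
        with a single iteration STD and CI are undefined (NaN)."""
        rows = []
        for cohort, grp in self.records.groupby("cohort"):
            n = len(grp)
            for m in METRICS:
                vals = grp[m].to_numpy()
                mean = float(vals.mean())
                sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
                if n > 1 and sd > 0:
                    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
                    lo, hi = mean - half, mean + half
                elif n > 1:
                    lo = hi = mean
                else:
                    lo = hi = float("nan")
                rows.append(
                    {"model": self.model_tag, "cohort": cohort, "metric": m,
                     "mean": mean, "std": sd, "ci_lower": lo, "ci_upper": hi,
                     "n_iterations": n}
                )
        return pd.DataFrame(rows)

    def test_aucs(self) -> np.ndarray:
        grp = self.records[self.records["cohort"] == "test"].sort_values("iteration")
        return grp["AUC"].to_numpy()


def repeated_evaluation(
    features: pd.DataFrame,
    labels,
    n_iter: int = 30,
    train_frac: float = 0.7,
    selection_cfg=None,
    ridge_cfg: RidgeConfig | None = None,
    seed: int = 0,
    model_tag: str = "model",
    scoring_cohort: str = "test",
) -> EvalReport:
    """Repeated stratified 7:3 evaluation with per-iteration selection.

    Each iteration: stratified split, standardization fitted on the train
    cohort, the full selection protocol (screen, rank/prune, prefix search)
    when ``selection_cfg`` is given, ridge fit, metrics on both cohorts.
    Iteration i uses ``seed + i`` for every stochastic step, so a fixed seed
    reproduces the report exactly.
    """
    from .feature_selection import select_features, standardize

    ridge_cfg = ridge_cfg or RidgeConfig()
    y = np.asarray(labels).astype(int)
    rows = []
    selected_last: list[str] = []
    for i in range(n_iter):
        idx_train, idx_test = train_test_split(
            np.arange(len(y)),
            train_size=train_frac,
            stratify=y,
            random_state=seed + i,
        )
        x_train = features.iloc[idx_train]
        x_test = features.iloc[idx_test]
        y_train, y_test = y[idx_train], y[idx_test]
        z_train = standardize(x_train)
        z_test = standardize(x_train, x_test)
        if selection_cfg is not None:
            cols, _ = select_features(
                z_train, y_train, z_test, y_test,
                cfg=selection_cfg, ridge_cfg=ridge_cfg, seed=seed + i,
                scoring_cohort=scoring_cohort,
            )
            if not cols:  # nothing survived screening: fall back to all
                cols = list(features.columns)
        else:
            cols = list(features.columns)
        model = fit_ridge(z_train[cols], y_train, ridge_cfg, seed=seed + i)
        for cohort, zx, yy in (("train", z_train, y_train), ("test", z_test, y_test)):
            rec = evaluate(model, zx[cols], yy)
            rec.update({"iteration": i, "cohort": cohort, "n_features": len(cols)})
            rows.append(rec)
        selected_last = cols
    return EvalReport(
        model_tag=model_tag,
        records=pd.DataFrame(rows),
        selected_features=selected_last,
    )


# ---------------------------------------------------------------------------
# AUC confidence intervals

def delong_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance via placement values."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    # placement of each positive among negatives and vice versa
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / len(neg) for p in pos])
    v01 = np.array([((pos > n).sum() + 0.5 * (pos == n).sum()).item() / len(pos) for n in neg])
    auc = float(v10.mean())
    var = 0.0
    if len(pos) > 1:
        var += v10.var(ddof=1) / len(pos)
    if len(neg) > 1:
        var += v01.var(ddof=1) / len(neg)
    return auc, float(var)


def auc_ci(
    scores,
    labels,
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """95% CI of the AUC, by stratified bootstrap (default) or DeLong.

    The bootstrap draws ``n_boot`` resamples within each class and takes
    percentile bounds; DeLong uses the analytic placement-value variance
    with a normal interval.  Bounds are clipped to [0, 1].
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    alpha = 1.0 - level
    if method == "delong":
        auc, var = delong_variance(s, y)
        if var == 0:
            warnings.warn("zero DeLong variance; CI degenerates to the point AUC")
        half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(var)
        lo, hi = auc - half, auc + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        ipos = np.flatnonzero(y == 1)
        ineg = np.flatnonzero(y == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(ipos, len(ipos), replace=True)
            bn = rng.choice(ineg, len(ineg), replace=True)
            idx = np.concatenate([bp, bn])
            aucs[b] = roc_auc_score(y[idx], s[idx])
        lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        raise ValueError("method must be 'delong' or 'bootstrap'")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def paired_model_test(metrics_a, metrics_b) -> float:
    """Two-sided paired Student t-test on per-iteration metrics.

    Identical vectors (all differences zero) return p = 1.0 by convention.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired vectors with >= 2 entries")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if not np.allclose(d, 0.0):
            warnings.warn("constant nonzero difference; t-test degenerate")
            return 0.0
        warnings.warn("zero-variance differences; reporting p = 1.0 (exact tie)")
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


# ---------------------------------------------------------------------------
# Decision curve analysis

@dataclass(frozen=True)
class NetBenefitCurve:
    """Net benefit of a model against treat-all / treat-none references."""

    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "model": self.net_benefit,
             "treat_all": self.treat_all, "treat_none": self.treat_none}
        )


def net_benefit_curve(probabilities, labels, thresholds=None) -> NetBenefitCurve:
    """Decision-curve analysis: ``NB(t) = TP/n - (FP/n) * t / (1 - t)``.

    ``treat_all`` is the curve of labelling every patient positive,
    ``pi - (1 - pi) * t / (1 - t)``; treat-none is identically zero.
    ``t = 1`` is excluded from the grid.
    """
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels).astype(int)
    t = (
        np.linspace(0.01, 0.99, 99)
        if thresholds is None
        else np.asarray(thresholds, dtype=float)
    )
    if ((t <= 0) | (t >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    pi = y.mean()
    nb = np.empty_like(t)
    for k, thr in enumerate(t):
        pred = p >= thr
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        nb[k] = tp - fp * thr / (1.0 - thr)
    treat_all = pi - (1.0 - pi) * t / (1.0 - t)
    return NetBenefitCurve(
        thresholds=t, net_benefit=nb, treat_all=treat_all,
        treat_none=np.zeros_like(t),
    )
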