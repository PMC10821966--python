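"""Stability feature selection by resampling frequency.

The selection protocol, applied independently inside every train/test
iteration of the evaluation harness:

1. standardize features (train mean/SD, z-scores);
2. draw 100 stratified 70% subsamples of the training cohort without
   replacement; in each, drop zero-variance columns and keep features whose
   two-sample Student t-test (equal variances, two-sided) against the
   outcome has p < 0.01;
3. score each feature by its retention frequency ``f_i = sum_i x_i / 100``;
4. keep the top 10% (at least 40) by frequency, then greedily remove
   features correlated (|Pearson r| > 0.5 on the training data) with an
   already-kept, higher-frequency feature;
5. evaluate nested prefixes (top-1, top-2, ... by frequency rank) with the
   ridge classifier and keep the prefix with the best test-cohort AUC.

Step 5 follows the original protocol of choosing the prefix on the test
cohort, which leaks test information into model selection; a nested mode
that scores prefixes by cross-validation inside the training cohort is
available via ``prefix_search(..., scoring_cohort="train_cv")``.

Frequency ties are broken by mean |t| across resamples, then by feature
name, so the ranking is deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionConfig",
    "SelectionTrace",
    "standardize",
    "resample_screen",
    "rank_and_prune",
    "prefix_search",
    "select_features",
]


@dataclass(frozen=True)
class SelectionConfig:
    n_resamples: int = 100
    frac: float = 0.7
    p_thresh: float = 0.01
    top_frac: float = 0.10
    min_keep: int = 40
    r_thresh: float = 0.5


@dataclass
class SelectionTrace:
    """Per-resample retention indicators and derived frequency ranking."""

    kept: pd.DataFrame  # resample x feature, bool
    frequency: pd.Series = field(init=False)
    mean_abs_t: pd.Series = field(init=False)
    ranked: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.frequency = self.kept.mean(axis=0)
        t = self._abs_t if self._abs_t is not None else pd.DataFrame(
            0.0, index=self.kept.index, columns=self.kept.columns
        )
        self.mean_abs_t = t.mean(axis=0)
        surv = self.frequency[self.frequency > 0]
        # stable sort on a name-sorted frame: ties in (f, mean|t|) break
        # lexicographically by feature name
        order = (
            pd.DataFrame({"f": surv, "t": self.mean_abs_t[surv.index]})
            .sort_index(kind="mergesort")
            .sort_values(["f", "t"], ascending=False, kind="mergesort")
        )
        self.ranked = list(order.index)

    _abs_t: pd.DataFrame | None = None


def standardize(train: pd.DataFrame, apply_to: pd.DataFrame | None = None):
    """Z-score features using training-cohort mean and population SD.

    Zero-variance columns map to 0.  Returns the transformed ``apply_to``
    (default: the training frame itself).
    """
    if train.shape[0] == 0:
        raise ValueError("cannot standardize an empty training cohort")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0).replace(0.0, np.inf)  # constant -> 0 after div
    target = train if apply_to is None else apply_to
    return (target - mean) / sd


def _welchless_ttest(x: np.ndarray, y0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized equal-variance two-sample t-test over feature columns."""
    g1 = x[y0 == 1]
    g0 = x[y0 == 0]
    n1, n0 = len(g1), len(g0)
    m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
    v1 = g1.var(axis=0, ddof=1)
    v0 = g0.var(axis=0, ddof=1)
    dof = n1 + n0 - 2
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / dof
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / denom
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return t, p


def resample_screen(
    features: pd.DataFrame,
    labels,
    cfg: SelectionConfig = SelectionConfig(),
    seed: int = 0,
) -> SelectionTrace:
    """Univariate screening over stratified resamples; records ``f_i``.

    Resamples are stratified by label so every draw contains both classes
    (a non-stratified draw that lost a class would make the t-test
    undefined and is redrawn).
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("screening requires both outcome classes")
    x = features.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    k1 = max(1, int(round(cfg.frac * len(idx1))))
    k0 = max(1, int(round(cfg.frac * len(idx0))))

    kept = np.zeros((cfg.n_resamples, x.shape[1]), dtype=bool)
    abs_t = np.zeros_like(kept, dtype=float)
    for r in range(cfg.n_resamples):
        sub = np.concatenate(
            [rng.choice(idx1, k1, replace=False), rng.choice(idx0, k0, replace=False)]
        )
        xs, ys = x[sub], y[sub]
        variant = xs.var(axis=0) > 0
        t, p = _welchless_ttest(xs, ys)
        ok = variant & np.isfinite(p) & (p < cfg.p_thresh)
        kept[r] = ok
        abs_t[r, ok] = np.abs(t[ok])
    return SelectionTrace(
        kept=pd.DataFrame(kept, columns=features.columns),
        _abs_t=pd.DataFrame(abs_t, columns=features.columns),
    )


def rank_and_prune(
    trace: SelectionTrace,
    train: pd.DataFrame,
    cfg: SelectionConfig = SelectionConfig(),
) -> list[str]:
    """Frequency-rank retention followed by Pearson redundancy pruning.

    Keeps the top ``max(ceil(top_frac * m), min_keep)`` survivors (m =
    features with f > 0, capped at m), then greedily drops any feature with
    |r| > ``r_thresh`` against an already-kept, higher-ranked feature.
    """
    survivors = trace.ranked
    m = len(survivors)
    if m == 0:
        warnings.warn("no feature survived screening; selection is empty")
        return []
    k = min(m, max(math.ceil(cfg.top_frac * m), cfg.min_keep))
    head = survivors[:k]
    z = standardize(train[head]).to_numpy(dtype=float)
    n = z.shape[0]
    corr = np.abs(z.T @ z) / n  # |Pearson r| of z-scored columns
    keep: list[int] = []
    for i in range(len(head)):
        if all(corr[i, j] <= cfg.r_thresh for j in keep):
            keep.append(i)
    return [head[i] for i in keep]


def prefix_search(
    pruned: list[str],
    train: pd.DataFrame,
    train_labels,
    test: pd.DataFrame,
    test_labels,
    ridge_cfg=None,
    seed: int = 0,
    scoring_cohort: str = "test",
) -> tuple[list[str], float]:
    """Choose the best nested prefix (top-1, top-2, ...) of the pruned list.

    Fits the ridge classifier per prefix and returns the prefix with the
    largest AUC on the scoring cohort (ties favor the smaller subset).
    ``scoring_cohort="test"`` reproduces the original protocol;
    ``"train_cv"`` scores by stratified cross-validation inside the
    training cohort instead (no test leakage).
    """
    from .model_eval import RidgeConfig, evaluate, fit_ridge

    if not pruned:
        raise ValueError("prefix search requires a non-empty feature list")
    if scoring_cohort not in ("test", "train_cv"):
        raise ValueError("scoring_cohort must be 'test' or 'train_cv'")
    ridge_cfg = ridge_cfg or RidgeConfig()
    best: tuple[float, int] | None = None
    best_features: list[str] = []
    for k in range(1, len(pruned) + 1):
        cols = pruned[:k]
        if scoring_cohort == "test":
            model = fit_ridge(train[cols], train_labels, ridge_cfg, seed=seed)
            auc = evaluate(model, test[cols], test_labels)["AUC"]
        else:
            from sklearn.model_selection import StratifiedKFold, cross_val_score
            from sklearn.linear_model import LogisticRegression

            cv = StratifiedKFold(3, shuffle=True, random_state=seed)
            auc = float(
                cross_val_score(
                    LogisticRegression(max_iter=1000),
                    train[cols], np.asarray(train_labels),
                    cv=cv, scoring="roc_auc",
                ).mean()
            )
        if best is None or auc > best[0]:
            best = (auc, k)
            best_features = cols
    return best_features, best[0]


def select_features(
    train: pd.DataFrame,
    train_labels,
    test: pd.DataFrame,
    test_labels,
    cfg: SelectionConfig = SelectionConfig(),
    ridge_cfg=None,
    seed: int = 0,
    scoring_cohort: str = "test",
) -> tuple[list[str], SelectionTrace]:
    """Full pipeline: screen -> rank/prune -> prefix search."""
    trace = resample_screen(train, train_labels, cfg, seed=seed)
    pruned = rank_and_prune(trace, train, cfg)
    if not pruned:
        return [], trace
    chosen, _ = prefix_search(
        pruned, train, train_labels, test, test_labels,
        ridge_cfg=ridge_cfg, seed=seed, scoring_cohort=scoring_cohort,
    )
    return chosen, trace
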