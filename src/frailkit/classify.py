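"""Diagnostic evaluation: single-feature LDA with repeated cross-validation.

A one-dimensional Gaussian equal-variance discriminant classifies diagnosis
pairs from an FI value.  Performance is summarised over repeated stratified
ten-fold cross-validation (optionally undersampling the larger class each
repeat), external validation scores a fixed development-sample model on
validation folds, and paired t-tests compare FI variants repeat-by-repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LDAModel",
    "CVScheme",
    "MetricSet",
    "lda_train",
    "lda_posterior",
    "repeated_cv",
    "external_validate",
    "compare_classifiers",
]

METRICS = ("auc", "sensitivity", "specificity", "ppv", "npv", "f1")


@dataclass
class LDAModel:
    mu_pos: float
    mu_neg: float
    var: float             # pooled within-class variance
    prior_pos: float
    positive: object       # label of the positive (more impaired) class


@dataclass(frozen=True)
class CVScheme:
    folds: int = 10
    repeats: int = 100
    stratified: bool = True
    undersample: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class MetricSet:
    per_repeat: pd.DataFrame  # repeats x METRICS

    @property
    def mean(self) -> pd.Series:
        return self.per_repeat.mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_repeat.std(ddof=1) if len(self.per_repeat) > 1 else self.per_repeat.iloc[0] * 0.0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def lda_train(fi_values, labels, positive=None) -> LDAModel:
    """Fit the equal-variance Gaussian discriminant on one feature.

    ``positive`` names the class treated as "impaired"; defaults to the class
    with the larger mean feature value.
    """
    x = np.asarray(fi_values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if positive is None:
        means = {c: x[y == c].mean() for c in classes}
        positive = max(classes, key=lambda c: means[c])
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not present")
    pos, neg = x[y == positive], x[y != positive]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs >= 2 members")
    n_pos, n_neg = len(pos), len(neg)
    var = (((pos - pos.mean()) ** 2).sum() + ((neg - neg.mean()) ** 2).sum()) / (n_pos + n_neg - 2)
    if var <= 0:
        raise ValueError("zero pooled within-class variance")
    return LDAModel(
        mu_pos=float(pos.mean()),
        mu_neg=float(neg.mean()),
        var=float(var),
        prior_pos=n_pos / (n_pos + n_neg),
        positive=positive,
    )


def lda_posterior(model: LDAModel, fi_values) -> np.ndarray:
    """Posterior probability of the positive class under the fitted model."""
    x = np.asarray(fi_values, dtype=float)
    # log odds = (mu_p - mu_n)/var * x - (mu_p^2 - mu_n^2)/(2 var) + log prior odds
    a = (model.mu_pos - model.mu_neg) / model.var
    b = -(model.mu_pos**2 - model.mu_neg**2) / (2 * model.var)
    b += np.log(model.prior_pos / (1 - model.prior_pos))
    return 1.0 / (1.0 + np.exp(-(a * x + b)))


def _metrics_from_scores(y_true: np.ndarray, score: np.ndarray, pred: np.ndarray) -> dict:
    tp = int(((y_true == 1) & (pred == 1)).sum())
    tn = int(((y_true == 0) & (pred == 0)).sum())
    fp = int(((y_true == 0) & (pred == 1)).sum())
    fn = int(((y_true == 1) & (pred == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    f1 = 2 * ppv * sens / (ppv + sens) if (ppv + sens) and np.isfinite(ppv + sens) and ppv + sens > 0 else np.nan
    auc = roc_auc_score(y_true, score) if len(np.unique(y_true)) == 2 else np.nan
    return {"auc": auc, "sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv, "f1": f1}


def repeated_cv(fi_values, labels, scheme: CVScheme, positive=None) -> MetricSet:
    """Repeated stratified k-fold CV of the single-feature discriminant.

    Per repeat, out-of-fold predictions are pooled and one metric row computed.
    Classification (sensitivity/specificity/PPV/NPV/F1) thresholds the
    fold-model posterior at 0.5; the AUC ranks the fold-oriented marker
    (each fold's posterior is a strictly monotone transform of it, so ranks
    are identical within folds while the pooled AUC stays free of per-fold
    calibration offsets and equals the marker's Mann-Whitney AUC whenever the
    folds agree on direction).  With ``scheme.undersample``, the larger class
    is subsampled to the smaller (fresh draw per repeat) before partitioning.
    """
    x = np.asarray(fi_values, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if counts.min() < scheme.folds:
        raise ValueError("smallest class is smaller than the fold count")
    if positive is None:
        positive = lda_train(x, y).positive
    rng = np.random.default_rng(scheme.seed)
    rows = []
    for _ in range(scheme.repeats):
        if scheme.undersample:
            keep_idx = []
            m = counts.min()
            for c in classes:
                idx = np.where(y == c)[0]
                keep_idx.append(rng.choice(idx, size=m, replace=False) if len(idx) > m else idx)
            idx = np.sort(np.concatenate(keep_idx))
            xr, yr = x[idx], y[idx]
        else:
            xr, yr = x, y
        splitter = StratifiedKFold(
            n_splits=scheme.folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        strat = yr if scheme.stratified else np.zeros(len(yr), dtype=int)
        score = np.empty(len(xr))
        pred = np.empty(len(xr), dtype=int)
        for train, test in splitter.split(xr[:, None], strat):
            model = lda_train(xr[train], yr[train], positive=positive)
            post = lda_posterior(model, xr[test])
            direction = 1.0 if model.mu_pos >= model.mu_neg else -1.0
            score[test] = direction * xr[test]
            pred[test] = (post >= 0.5).astype(int)
        rows.append(_metrics_from_scores((yr == positive).astype(int), score, pred))
    return MetricSet(per_repeat=pd.DataFrame(rows, columns=list(METRICS)))


def external_validate(dev_fi, dev_labels, val_fi, val_labels, scheme: CVScheme, positive=None) -> MetricSet:
    """Score a fixed development-sample model on repeated validation folds.

    The discriminant is trained once on the full development sample; the
    validation sample is split into ``scheme.folds`` folds, each scored by the
    fixed model, for ``scheme.repeats`` fresh partitions.  Per-fold metric
    rows are aggregated into the usual mean (SD) summary.
    """
    val_fi = np.asarray(val_fi, dtype=float)
    val_labels = np.asarray(val_labels)
    if len(np.unique(val_labels)) != 2:
        raise ValueError("validation sample must contain both classes")
    model = lda_train(np.asarray(dev_fi, dtype=float), np.asarray(dev_labels), positive=positive)
    rng = np.random.default_rng(scheme.seed)
    rows = []
    for _ in range(scheme.repeats):
        splitter = StratifiedKFold(
            n_splits=scheme.folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
        )
        strat = val_labels if scheme.stratified else np.zeros(len(val_labels), dtype=int)
        for _, fold in splitter.split(val_fi[:, None], strat):
            post = lda_posterior(model, val_fi[fold])
            y_true = (val_labels[fold] == model.positive).astype(int)
            rows.append(_metrics_from_scores(y_true, post, (post >= 0.5).astype(int)))
    return MetricSet(per_repeat=pd.DataFrame(rows, columns=list(METRICS)))


@dataclass
class PairedTestResult:
    t: float | None
    df: int
    p: float | None
    mean_diff: float
    degenerate: bool = False


def compare_classifiers(metrics_a, metrics_b) -> PairedTestResult:
    """Paired t-test of two equal-length per-repeat metric vectors (a - b)."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1) if n > 1 else 0.0
    if sd == 0:
        return PairedTestResult(t=None, df=n - 1, p=None, mean_diff=float(d.mean()), degenerate=True)
    from scipy import stats

    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(t=float(t), df=n - 1, p=float(p), mean_diff=float(d.mean()))
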