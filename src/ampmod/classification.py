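"""Individualized binarization, LOSO SVM evaluation, fusion, significance.

Subjective ratings on the 9-point scale are binarized per subject with
an individualized threshold: the cut giving the most balanced high/low
split for that subject (a global cut at 5 leaves a roughly 60/40
imbalance because raters use the scale differently).  Classification is
a leave-one-sample-out (LOSO) RBF-kernel SVM with fixed default
parameters (C = 1, gamma = 0.01), features z-scored from the training
fold only.  The figure of merit is balanced accuracy,
BACC = (SENS + SPEC) / 2, and significance is assessed with a
one-sample t-test of the observed BACC against the empirical BACC
distribution of a uniform random voter on the same labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

__all__ = [
    "individualized_threshold",
    "binarize_ratings",
    "loso_evaluate",
    "fuse_features",
    "fuse_decisions",
    "significance_vs_random",
    "EvaluationResult",
    "DEFAULT_SVM_C",
    "DEFAULT_SVM_GAMMA",
]

DEFAULT_SVM_C = 1.0
DEFAULT_SVM_GAMMA = 0.01


def individualized_threshold(ratings) -> float:
    """Rating cut giving the most balanced high/low split.

    ``high`` means rating >= threshold.  Candidate thresholds are the
    distinct observed ratings; among cuts with equal imbalance the one
    closest to the scale midpoint (5) wins.  All-equal ratings cannot be
    binarized and raise.
    """
    r = np.asarray(ratings, dtype=float)
    values = np.unique(r)
    if len(values) < 2:
        raise ValueError("cannot binarize: all ratings identical")
    best = None
    for t in values[1:]:  # t = min would put everything in 'high'
        high = int((r >= t).sum())
        imbalance = abs(2 * high - len(r))
        key = (imbalance, abs(t - 5.0), t)
        if best is None or key < best[0]:
            best = (key, t)
    return float(best[1])


def binarize_ratings(ratings: pd.DataFrame, dimension: str) -> pd.DataFrame:
    """Per-subject binary labels for one affective dimension.

    Returns a frame indexed by (subject, trial) with columns ``label``
    (0 = low, 1 = high) and ``threshold`` (the subject's cut).
    """
    rows = []
    for subject, grp in ratings.groupby("subject", sort=False):
        t = individualized_threshold(grp[dimension])
        for _, row in grp.iterrows():
            rows.append((subject, int(row["trial"]),
                         int(row[dimension] >= t), t))
    out = pd.DataFrame(rows, columns=["subject", "trial", "label", "threshold"])
    return out.set_index(["subject", "trial"])


@dataclass
class EvaluationResult:
    """Per-fold predictions and derived performance measures."""

    predictions: pd.Series
    labels: pd.Series
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    p_value: float | None = None

    def __post_init__(self):
        y = np.asarray(self.labels)
        yhat = np.asarray(self.predictions)
        self.tp = int(np.sum((yhat == 1) & (y == 1)))
        self.fp = int(np.sum((yhat == 1) & (y == 0)))
        self.tn = int(np.sum((yhat == 0) & (y == 0)))
        self.fn = int(np.sum((yhat == 0) & (y == 1)))

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def summary(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "p_value": self.p_value,
        }


def loso_evaluate(features: pd.DataFrame, labels,
                  svm_c: float = DEFAULT_SVM_C,
                  svm_gamma: float = DEFAULT_SVM_GAMMA) -> EvaluationResult:
    """Leave-one-sample-out evaluation of an RBF-kernel SVM.

    Each trial is predicted by a model trained on all other trials
    (pooled across subjects).  Features are z-scored with the training
    fold's mean and standard deviation only, so no information from the
    held-out trial reaches the model.  Folds whose training set is
    single-class are skipped with a warning.
    """
    y = pd.Series(np.asarray(labels), index=features.index)
    X = features.to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 trials for LOSO")
    preds = {}
    yv = y.to_numpy()
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = yv[mask]
        if len(np.unique(ytr)) < 2:
            warnings.warn(f"fold {i}: single-class training set; skipped")
            continue
        mu = X[mask].mean(axis=0)
        sd = X[mask].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(C=svm_c, gamma=svm_gamma, kernel="rbf")
        clf.fit((X[mask] - mu) / sd, ytr)
        preds[features.index[i]] = int(clf.predict(((X[i] - mu) / sd)[None])[0])
    pred = pd.Series(preds)
    pred.index = pd.MultiIndex.from_tuples(pred.index,
                                           names=features.index.names) \
        if isinstance(features.index, pd.MultiIndex) else pred.index
    return EvaluationResult(predictions=pred, labels=y.loc[pred.index])


def fuse_features(tables: list[pd.DataFrame],
                  prefixes: list[str] | None = None) -> pd.DataFrame:
    """Feature-level fusion: column concatenation of row-aligned tables.

    Optional per-table prefixes keep column names disjoint when the same
    naming convention is used by more than one family.
    """
    if not tables:
        raise ValueError("no tables to fuse")
    base = tables[0].index
    for t in tables[1:]:
        if not t.index.equals(base):
            raise ValueError("tables are not row-aligned on (subject, trial)")
    if prefixes is not None:
        if len(prefixes) != len(tables):
            raise ValueError("one prefix per table required")
        tables = [t.add_prefix(f"{p}:") if p else t
                  for t, p in zip(tables, prefixes)]
    out = pd.concat(tables, axis=1)
    if out.columns.duplicated().any():
        dupes = out.columns[out.columns.duplicated()].tolist()
        raise ValueError(f"fused tables share column names: {dupes[:5]}")
    return out


def fuse_decisions(predictions: list[pd.Series]) -> pd.Series:
    """Decision-level fusion: per-trial majority vote of exactly three
    aligned binary predictions (three voters make ties impossible)."""
    if len(predictions) != 3:
        raise ValueError("decision fusion requires exactly 3 voters")
    base = predictions[0].index
    for p in predictions[1:]:
        if not p.index.equals(base):
            raise ValueError("predictions are not aligned")
    votes = np.stack([np.asarray(p) for p in predictions])
    return pd.Series((votes.sum(axis=0) >= 2).astype(int), index=base)


def significance_vs_random(result: EvaluationResult, reps: int = 1000,
                           seed: int | None = None) -> float:
    """p-value of the observed BACC against a uniform random voter.

    The random voter predicts each trial's class by a fair coin flip;
    its BACC distribution on the same labels is simulated ``reps`` times
    and a two-sided one-sample t-test compares it with the observed
    BACC.  Chance-level performance gives p near 1; BACC near 1 on a
    reasonable number of trials gives a vanishing p.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(result.labels)
    n = len(y)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    baccs = np.empty(reps)
    for r in range(reps):
        flip = rng.integers(0, 2, size=n)
        sens = np.sum(flip[pos] == 1) / n_pos if n_pos else np.nan
        spec = np.sum(flip[~pos] == 0) / n_neg if n_neg else np.nan
        baccs[r] = (sens + spec) / 2.0
    observed = result.balanced_accuracy
    if np.std(baccs) == 0:
        return 1.0 if np.isclose(baccs.mean(), observed) else 0.0
    t = stats.ttest_1samp(baccs, popmean=observed)
    result.p_value = float(t.pvalue)
    return float(t.pvalue)
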