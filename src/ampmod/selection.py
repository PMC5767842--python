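"""Multi-stage feature selection: ANOVA pre-screen then mRMR.

A fraction (25% by default) of each subject's trials is set aside as a
ranking set; selection runs only on that set so the later cross-
validated evaluation never sees the trials that chose its features.  On
the ranking set, a one-way ANOVA against the binary labels keeps
features with p < 0.1, and greedy minimum-redundancy maximum-relevance
(mRMR) forward selection ranks the survivors: at each step the feature
maximizing MI(feature; label) minus the mean MI with already-selected
features is added.  Mutual information uses the same 50-bin equal-width
histogram estimator as the AMI features.

For the fair-comparison mode, every feature class is truncated to the
number of benchmark (SF) features that passed the ANOVA screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .amf_features import DEFAULT_HIST_BINS, _digitize, _entropy

__all__ = [
    "holdout_split",
    "anova_prescreen",
    "mrmr_select",
    "equalized_budget",
    "SelectionResult",
    "mutual_information",
]

DEFAULT_ALPHA = 0.1
DEFAULT_SPLIT_FRACTION = 0.25


def holdout_split(trials: pd.MultiIndex | list,
                  labels: pd.Series,
                  fraction: float = DEFAULT_SPLIT_FRACTION,
                  seed: int | None = None):
    """Per-subject stratified split into (ranking, evaluation) trial ids.

    ``trials`` is a (subject, trial) index; ``labels`` the binary class
    per trial.  Roughly ``fraction`` of each subject's trials — balanced
    across classes where possible — go to the ranking set; the rest form
    the evaluation set.  The two sets are disjoint by construction.
    """
    if not isinstance(trials, pd.MultiIndex):
        trials = pd.MultiIndex.from_tuples(list(trials),
                                           names=["subject", "trial"])
    labels = pd.Series(np.asarray(labels), index=trials)
    rng = np.random.default_rng(seed)
    ranking: list[tuple] = []
    for subject in trials.get_level_values(0).unique():
        sub = labels.xs(subject, level=0, drop_level=False)
        n_take = int(round(fraction * len(sub)))
        classes = sub.unique()
        if len(classes) < 2:
            warnings.warn(f"subject {subject} has a single class; "
                          "unstratified split used")
            take = rng.choice(len(sub), size=n_take, replace=False)
            ranking.extend(sub.index[i] for i in take)
            continue
        # per-class quota, largest-remainder rounding to hit n_take exactly
        quota = {}
        sizes = {c: int((sub == c).sum()) for c in classes}
        raw = {c: fraction * sizes[c] for c in classes}
        base = {c: int(np.floor(raw[c])) for c in classes}
        rem = n_take - sum(base.values())
        order = sorted(classes, key=lambda c: raw[c] - base[c], reverse=True)
        for c in classes:
            quota[c] = base[c]
        for c in order[:max(0, rem)]:
            quota[c] += 1
        for c in classes:
            idx = np.flatnonzero((sub == c).to_numpy())
            take = rng.choice(idx, size=min(quota[c], len(idx)), replace=False)
            ranking.extend(sub.index[i] for i in take)
    ranking_ids = pd.MultiIndex.from_tuples(ranking,
                                            names=["subject", "trial"]) \
        if ranking else pd.MultiIndex.from_tuples([], names=["subject", "trial"])
    eval_ids = trials[~trials.isin(ranking_ids)]
    return ranking_ids, eval_ids


def anova_prescreen(features: pd.DataFrame, labels,
                    alpha: float = DEFAULT_ALPHA):
    """One-way ANOVA per feature column; keep p < alpha.

    Implemented from between/within sums of squares.  Constant features
    (or features constant within the pooled sample) have an undefined
    F statistic and are dropped with a note.  Returns (surviving names,
    p-value Series over all testable columns).
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    grand = np.nanmean(X, axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    df_between = len(classes) - 1
    df_within = n - len(classes)
    for c in classes:
        g = X[y == c]
        gm = np.nanmean(g, axis=0)
        ss_between += len(g) * (gm - grand) ** 2
        ss_within += np.nansum((g - gm) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_between) / (ss_within / df_within)
    p = stats.f.sf(F, df_between, df_within)
    pvals = pd.Series(p, index=features.columns)
    degenerate = ~np.isfinite(F) | (ss_within + ss_between <= 0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} constant/degenerate features "
                      "dropped from the ANOVA screen")
    keep = features.columns[(~degenerate) & (p < alpha)]
    return list(keep), pvals


def mutual_information(x, y, bins: int = DEFAULT_HIST_BINS) -> float:
    """Histogram mutual information (nats) between a continuous feature
    (equal-width binned) and a second variable (binned likewise, or used
    as-is if already small-integer coded)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    dx = _digitize(x, bins)
    if dx is None:
        return 0.0
    if np.issubdtype(y.dtype, np.integer) and y.max() < bins:
        dy = y.astype(np.intp)
    else:
        dy = _digitize(y.astype(float), bins)
        if dy is None:
            return 0.0
    ny = int(dy.max()) + 1
    hx = _entropy(np.bincount(dx, minlength=bins))
    hy = _entropy(np.bincount(dy, minlength=ny))
    hxy = _entropy(np.bincount(dx * ny + dy, minlength=bins * ny))
    return max(0.0, hx + hy - hxy)


@dataclass
class SelectionResult:
    """Outcome of the multi-stage selection."""

    ranked: list[str]
    pvalues: pd.Series
    scores: list[float] = field(default_factory=list)
    ranking_ids: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.ranked) + 1),
            "name": self.ranked,
            "p_value": [self.pvalues.get(n, np.nan) for n in self.ranked],
            "mrmr_score": self.scores if self.scores else np.nan,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def mrmr_select(features: pd.DataFrame, labels, k: int,
                bins: int = DEFAULT_HIST_BINS) -> SelectionResult:
    """Greedy minimum-redundancy maximum-relevance forward selection.

    Step 1 picks the feature with maximal MI with the label; each later
    step adds the candidate maximizing ``MI(f; label) - mean MI(f, s)``
    over already-selected s.  Ties break lexicographically on the
    feature name, making the ranking deterministic.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    k = min(k, features.shape[1])
    names = list(features.columns)
    y = np.asarray(labels)
    if not np.issubdtype(y.dtype, np.integer):
        _, y = np.unique(y, return_inverse=True)
    cols = {n: features[n].to_numpy(dtype=float) for n in names}
    relevance = {n: mutual_information(cols[n], y, bins) for n in names}
    selected: list[str] = []
    scores: list[float] = []
    pair_mi: dict[tuple[str, str], float] = {}
    remaining = set(names)
    redundancy_sum = {n: 0.0 for n in names}
    while len(selected) < k and remaining:
        best_name, best_score = None, -np.inf
        for n in sorted(remaining):
            if selected:
                score = relevance[n] - redundancy_sum[n] / len(selected)
            else:
                score = relevance[n]
            if score > best_score + 1e-12:
                best_name, best_score = n, score
        selected.append(best_name)
        scores.append(best_score)
        remaining.discard(best_name)
        for n in remaining:
            mi = mutual_information(cols[n], cols[best_name], bins)
            pair_mi[(n, best_name)] = mi
            redundancy_sum[n] += mi
    return SelectionResult(ranked=selected, pvalues=pd.Series(dtype=float),
                           scores=scores)


def equalized_budget(selected_sf_count: int) -> int:
    """Feature budget for the fair-comparison mode: every feature class
    is truncated to the number of SF survivors.  Zero survivors disables
    the comparison mode (returns 0 with a warning)."""
    if selected_sf_count <= 0:
        warnings.warn("no SF features passed the screen; "
                      "equalized-comparison mode disabled")
        return 0
    return int(selected_sf_count)
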