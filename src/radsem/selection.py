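"""Spearman-redundancy pruning of the radiomic feature table.

Feature pairs with |rho| >= threshold (default 0.85) are treated as
redundant; within each such pair the member with the highest average |rho|
against the currently retained features is excluded.  The procedure is
greedy largest-pair-first with lexicographic tie-breaks, which makes it
deterministic and order-invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "spearman_matrix",
    "prune_redundant",
    "SelectionReport",
    "DroppedFeature",
    "SpearmanRedundancyFilter",
]

logger = logging.getLogger(__name__)


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Midrank Spearman correlation of every feature pair.

    NaN feature values are excluded pairwise (pairwise-complete
    observations); constant columns get NaN correlations and are flagged.
    """
    if len(table) < 3:
        raise ValueError(f"need at least 3 subjects, got {len(table)}")
    corr = table.corr(method="spearman")  # midranks, pairwise-complete
    np.fill_diagonal(corr.values, 1.0)
    constant = [c for c in table.columns if table[c].nunique(dropna=True) <= 1]
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = 1.0
        logger.warning("constant feature column %r: correlations undefined", c)
    return corr


@dataclass
class DroppedFeature:
    name: str
    reason: str                    # "redundant" or "constant"
    trigger_pair: tuple[str, str] | None
    trigger_rho: float
    mean_abs_rho_at_drop: float


@dataclass
class SelectionReport:
    """Outcome of redundancy pruning: kept names plus per-drop evidence."""

    kept: list[str]
    dropped: list[DroppedFeature]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "feature": d.name,
            "reason": d.reason,
            "trigger_feature": d.trigger_pair[1] if d.trigger_pair else "",
            "trigger_abs_rho": d.trigger_rho,
            "mean_abs_rho_at_drop": d.mean_abs_rho_at_drop,
        } for d in self.dropped]
        return pd.DataFrame(rows, columns=["feature", "reason", "trigger_feature",
                                           "trigger_abs_rho", "mean_abs_rho_at_drop"])


def prune_redundant(corr: pd.DataFrame, threshold: float = 0.85) -> SelectionReport:
    """Greedy removal of redundant features from a correlation matrix.

    Repeatedly: find the not-yet-dropped pair with the largest |rho| >=
    threshold (lexicographic tie-break on the pair), then drop the member
    with the larger mean |rho| against all currently retained features
    (lexicographically later name on a tie).  Constant columns (all-NaN
    correlations) are force-dropped first with reason ``"constant"``; NaNs
    count as 0 in mean-|rho| computations.
    """
    names = list(corr.columns)
    absr = corr.abs().to_numpy(dtype=float).copy()
    np.fill_diagonal(absr, np.nan)

    dropped: list[DroppedFeature] = []
    alive = dict.fromkeys(names, True)

    # constant columns: every off-diagonal entry NaN
    for i, n in enumerate(names):
        off = np.delete(absr[i], i)
        if off.size and np.all(np.isnan(off)):
            alive[n] = False
            dropped.append(DroppedFeature(n, "constant", None, np.nan, 0.0))

    def alive_idx():
        return [i for i, n in enumerate(names) if alive[n]]

    while True:
        idx = alive_idx()
        if len(idx) < 2:
            break
        sub = absr[np.ix_(idx, idx)]
        filled = np.nan_to_num(sub, nan=0.0)
        np.fill_diagonal(filled, 0.0)
        best = filled.max()
        if best < threshold:
            break
        # lexicographically first among maximal pairs
        cand = np.argwhere(np.isclose(filled, best))
        pairs = sorted(
            {tuple(sorted((names[idx[a]], names[idx[b]]))) for a, b in cand if a != b}
        )
        fa, fb = pairs[0]
        means = {}
        for f in (fa, fb):
            i = names.index(f)
            others = [j for j in idx if j != i]
            row = np.nan_to_num(absr[i, others], nan=0.0)
            means[f] = float(row.mean()) if others else 0.0
        # tolerance on the mean comparison: float summation order must not
        # decide a drop, only the documented lexicographic rule may
        if means[fa] - means[fb] > 1e-12 or (abs(means[fa] - means[fb]) <= 1e-12 and fa > fb):
            victim, partner = fa, fb
        else:
            victim, partner = fb, fa
        alive[victim] = False
        dropped.append(DroppedFeature(victim, "redundant", (victim, partner),
                                      float(best), means[victim]))

    kept = [n for n in names if alive[n]]
    # post-condition audit: no retained pair at or above threshold
    if len(kept) >= 2:
        ki = [names.index(n) for n in kept]
        resid = np.nan_to_num(absr[np.ix_(ki, ki)], nan=0.0)
        np.fill_diagonal(resid, 0.0)
        assert resid.max() < threshold, "pruning audit failed"
    return SelectionReport(kept=kept, dropped=dropped, threshold=float(threshold))


class SpearmanRedundancyFilter(BaseEstimator, TransformerMixin):
    """Feature selector dropping one member of every |rho| >= threshold pair.

    Fitted attributes
    -----------------
    correlation_matrix_ : DataFrame
        Midrank Spearman correlations of the training table.
    report_ : SelectionReport
        Kept/dropped features with the pairwise evidence for each drop.
    support_ : ndarray of bool
        Mask of retained columns, aligned with the fit-time column order.
    """

    def __init__(self, threshold: float = 0.85):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None) -> "SpearmanRedundancyFilter":
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.correlation_matrix_ = spearman_matrix(X)
        self.report_ = prune_redundant(self.correlation_matrix_, self.threshold)
        kept = set(self.report_.kept)
        self.support_ = np.array([c in kept for c in X.columns])
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def get_feature_names_out(self, input_features=None):
        return self.feature_names_in_[self.support_]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        return X[self.report_.kept]
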