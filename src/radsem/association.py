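"""Association engine linking radiomic features to semantic scores.

Binary semantic features (cavitation, air bronchogram, calcification) are
screened with the ROC AUC of the radiomic feature against presence/absence.
AUC > 0.5 means direct proportionality (higher feature value with presence);
AUC < 0.5 means inverse proportionality, reported as the *folded* value
1 - AUC, so folded AUCs live in [0.5, 1] with the direction kept separately.
Significance of AUC != 0.5 uses Noether's asymptotic normal test with the
null variance (n0 + n1 + 1) / (12 n0 n1).

Categorical (ordinal) semantic features are screened with the midrank
Spearman rho (strength and direction) and the tie-corrected Kruskal-Wallis
test (significance).

Within each semantic feature, p-values across all radiomic features form one
family and are Benjamini-Hochberg adjusted; q <= alpha (default 0.05) flags
significance.  Strength labels follow the conventional bins: AUC
(0.5, 0.7] weak, (0.7, 0.9] moderate, (0.9, 1] excellent (0.5 exactly is
"random"); |rho| <= 0.5 weak, (0.5, 0.7] moderate, (0.7, 0.9] high,
> 0.9 excellent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .semantic import BINARY_FEATURES, CATEGORICAL_FEATURES, CohortTable

__all__ = [
    "folded_auc",
    "noether_test",
    "categorical_association",
    "bh_adjust",
    "classify_strength",
    "build_report",
    "AssociationReport",
    "AssociationScreen",
]

logger = logging.getLogger(__name__)

#: minimum usable paired observations per test; below this the cell is
#: reported as not-evaluated
MIN_N_PER_TEST = 10


def _drop_nan_pairs(values, labels):
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    ok = ~np.isnan(v)
    return v[ok], y[ok]


def folded_auc(values, labels) -> tuple[float, float, str]:
    """ROC AUC of ``values`` against binary ``labels`` with folding.

    Returns ``(auc_raw, auc_folded, direction)``.  The raw AUC is the
    midrank Mann-Whitney statistic with class 1 ("presence") as positive;
    ties get half credit.  Direction is ``"proportional"`` iff
    auc_raw >= 0.5 (exact ties fold to proportional by convention).
    """
    v, y = _drop_nan_pairs(values, labels)
    y = y.astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    ranks = stats.rankdata(v)  # midranks
    r1 = ranks[y == 1].sum()
    auc_raw = float((r1 - n1 * (n1 + 1) / 2.0) / (n0 * n1))
    if auc_raw >= 0.5:
        return auc_raw, auc_raw, "proportional"
    return auc_raw, 1.0 - auc_raw, "inverse"


def noether_test(auc_raw: float, n0: int, n1: int) -> float:
    """Two-sided p for AUC != 0.5 via the normal approximation.

    z = (AUC - 0.5) / sqrt((n0 + n1 + 1) / (12 n0 n1)), the Mann-Whitney
    null variance on the AUC scale.
    """
    if n0 < 1 or n1 < 1:
        raise ValueError("both classes need at least one observation")
    se = np.sqrt((n0 + n1 + 1) / (12.0 * n0 * n1))
    z = (auc_raw - 0.5) / se
    return float(2.0 * stats.norm.sf(abs(z)))


def categorical_association(values, scores) -> tuple[float, float, float]:
    """Spearman rho plus Kruskal-Wallis (H, p) of values across score groups."""
    v, s = _drop_nan_pairs(values, scores)
    s = s.astype(int)
    groups = [v[s == g] for g in np.unique(s)]
    if len(groups) < 2:
        raise ValueError("need at least 2 distinct score groups")
    rho = float(stats.spearmanr(v, s).statistic)
    try:
        h, p = stats.kruskal(*groups)
    except ValueError:  # all values identical: H = 0, no evidence
        h, p = 0.0, 1.0
    return rho, float(h), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values stay NaN."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def classify_strength(kind: str, value: float) -> str:
    """Interpretation bin for a folded AUC or a Spearman rho."""
    if kind == "auc":
        if not 0.5 <= value <= 1.0:
            raise ValueError(f"folded AUC must lie in [0.5, 1], got {value}")
        if value == 0.5:
            return "random"
        if value <= 0.7:
            return "weak"
        if value <= 0.9:
            return "moderate"
        return "excellent"
    if kind == "rho":
        a = abs(value)
        if a > 1.0:
            raise ValueError(f"|rho| must be <= 1, got {value}")
        if a <= 0.5:
            return "weak"
        if a <= 0.7:
            return "moderate"
        if a <= 0.9:
            return "high"
        return "excellent"
    raise ValueError(f"unknown strength kind {kind!r}")


@dataclass
class AssociationReport:
    """Long-format binary and categorical association tables.

    ``binary`` columns: radiomic, semantic, auc_raw, auc_folded, direction,
    p, q, strength, significant, n.  ``categorical`` columns: radiomic,
    semantic, rho, kw_statistic, p, q, strength, significant, n.
    """

    binary: pd.DataFrame
    categorical: pd.DataFrame
    alpha: float
    skipped: list[str] = field(default_factory=list)

    def to_long_frame(self) -> pd.DataFrame:
        b = self.binary.assign(statistic_type="auc",
                               estimate=self.binary["auc_folded"])
        c = self.categorical.assign(statistic_type="rho", direction="",
                                    estimate=self.categorical["rho"])
        cols = ["radiomic", "semantic", "statistic_type", "estimate",
                "direction", "p", "q", "strength", "significant"]
        return pd.concat([b[cols], c[cols]], ignore_index=True)

    def summary(self) -> pd.DataFrame:
        """Per-semantic headline: significant count and the estimate range
        among significant cells."""
        rows = []
        for sem in BINARY_FEATURES:
            sub = self.binary[self.binary["semantic"] == sem]
            if sub.empty:
                continue
            sig = sub[sub["significant"]]
            rows.append({
                "semantic": sem, "type": "binary", "n_tests": len(sub),
                "n_significant": int(sig.shape[0]),
                "min_estimate": sig["auc_folded"].min() if len(sig) else np.nan,
                "max_estimate": sig["auc_folded"].max() if len(sig) else np.nan,
            })
        for sem in CATEGORICAL_FEATURES:
            sub = self.categorical[self.categorical["semantic"] == sem]
            if sub.empty:
                continue
            sig = sub[sub["significant"]]
            rows.append({
                "semantic": sem, "type": "categorical", "n_tests": len(sub),
                "n_significant": int(sig.shape[0]),
                "min_estimate": sig["rho"].abs().min() if len(sig) else np.nan,
                "max_estimate": sig["rho"].abs().max() if len(sig) else np.nan,
            })
        return pd.DataFrame(rows)


def build_report(features: pd.DataFrame, cohort: CohortTable,
                 alpha: float = 0.05) -> AssociationReport:
    """Score every (radiomic, semantic) pair and assemble the report.

    BH adjustment is performed within each semantic feature's family (all
    radiomic tests against that one column).  Binary semantic columns with a
    single class are skipped with a warning; cells with fewer than
    ``MIN_N_PER_TEST`` usable pairs are reported with NaN statistics.
    """
    features = features.copy()
    features.index = features.index.astype(str)
    sem = cohort.frame.copy()
    sem.index = sem.index.astype(str)
    missing = set(features.index) ^ set(sem.index)
    if missing:
        raise ValueError(f"subject mismatch between tables: {sorted(missing)[:5]} ...")
    sem = sem.loc[features.index]

    skipped = cohort.degenerate_binary_columns()
    for col in skipped:
        logger.warning("binary semantic feature %r has a single class; skipped", col)

    bin_rows = []
    for semantic in BINARY_FEATURES:
        if semantic in skipped:
            continue
        y_all = sem[semantic].to_numpy()
        for radiomic in features.columns:
            v, y = _drop_nan_pairs(features[radiomic].to_numpy(), y_all)
            row = {"radiomic": radiomic, "semantic": semantic, "n": len(v)}
            if len(v) < MIN_N_PER_TEST or len(set(y)) < 2:
                row.update(auc_raw=np.nan, auc_folded=np.nan, direction="",
                           p=np.nan, strength="not-evaluated")
                logger.warning("cell (%s, %s) not evaluated (n=%d usable)",
                               radiomic, semantic, len(v))
            else:
                auc_raw, auc_folded, direction = folded_auc(v, y)
                p = noether_test(auc_raw, int((y == 0).sum()), int((y == 1).sum()))
                row.update(auc_raw=auc_raw, auc_folded=auc_folded,
                           direction=direction, p=p,
                           strength=classify_strength("auc", auc_folded))
            bin_rows.append(row)
    binary = pd.DataFrame(bin_rows, columns=["radiomic", "semantic", "auc_raw",
                                             "auc_folded", "direction", "p",
                                             "strength", "n"])

    cat_rows = []
    for semantic in CATEGORICAL_FEATURES:
        s_all = sem[semantic].to_numpy()
        for radiomic in features.columns:
            v, s = _drop_nan_pairs(features[radiomic].to_numpy(), s_all)
            row = {"radiomic": radiomic, "semantic": semantic, "n": len(v)}
            if len(v) < MIN_N_PER_TEST or len(set(s)) < 2:
                row.update(rho=np.nan, kw_statistic=np.nan, p=np.nan,
                           strength="not-evaluated")
                logger.warning("cell (%s, %s) not evaluated (n=%d usable)",
                               radiomic, semantic, len(v))
            else:
                rho, h, p = categorical_association(v, s)
                row.update(rho=rho, kw_statistic=h, p=p,
                           strength=classify_strength("rho", rho))
            cat_rows.append(row)
    categorical = pd.DataFrame(cat_rows, columns=["radiomic", "semantic", "rho",
                                                  "kw_statistic", "p",
                                                  "strength", "n"])

    for frame in (binary, categorical):
        frame["q"] = np.nan
        for semantic in frame["semantic"].unique():
            fam = frame["semantic"] == semantic
            frame.loc[fam, "q"] = bh_adjust(frame.loc[fam, "p"].to_numpy())
        frame["significant"] = frame["q"] <= alpha

    return AssociationReport(binary=binary, categorical=categorical,
                             alpha=alpha, skipped=skipped)


class AssociationScreen(BaseEstimator):
    """Estimator screening a radiomic feature table against semantic scores.

    ``fit(X, y)`` takes the subjects x radiomic-features table ``X`` and the
    semantic cohort ``y`` (a :class:`CohortTable` or a DataFrame with the
    nine semantic columns) and exposes the fitted report:

    Attributes
    ----------
    report_ : AssociationReport
    binary_ : DataFrame         folded-AUC table (radiomic x 3 binary)
    categorical_ : DataFrame    rho/KW table (radiomic x 6 categorical)
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y) -> "AssociationScreen":
        cohort = y if isinstance(y, CohortTable) else CohortTable.from_frame(y)
        self.report_ = build_report(pd.DataFrame(X), cohort, alpha=self.alpha)
        self.binary_ = self.report_.binary
        self.categorical_ = self.report_.categorical
        return self

    def summary(self) -> pd.DataFrame:
        return self.report_.summary()
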