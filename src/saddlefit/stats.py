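"""Repeated-measures statistics on the extracted features.

Each feature is reduced to one value per (subject, saddle level) cell —
by default the per-subject mean of that subject's cycle-level values at
that level — giving an n-subjects × 3 table. The omnibus comparison across
the three levels is the Friedman rank test; pairwise follow-ups use the
Wilcoxon signed-rank test with a Bonferroni factor of 3 (the number of
level pairs). Pairwise Pearson correlations between selected features are
bucketed as strong (|r| >= 0.7), moderate (0.5 <= |r| < 0.7), low
(0.3 <= |r| < 0.5) or negligible (|r| < 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata, wilcoxon

from saddlefit.features import FeatureTable

__all__ = [
    "build_condition_table",
    "friedman_test",
    "wilcoxon_posthoc_bonferroni",
    "pearson_categorize",
    "FriedmanResult",
    "PairwiseResult",
    "CorrelationReport",
    "ALPHA",
]

ALPHA = 0.05
PAIRS = [(1, 2), (1, 3), (2, 3)]  # low–moderate, low–high, moderate–high
PAIR_NAMES = {(1, 2): "low-moderate", (1, 3): "low-high", (2, 3): "moderate-high"}


def build_condition_table(table: FeatureTable, feature: str,
                          per_cycle: bool = False) -> pd.DataFrame:
    """One value per (subject, level) for ``feature``: the mean of that
    subject's cycle-level values at that level.

    With ``per_cycle=True`` the raw cycle-level rows are returned instead
    (subject/level/value long format) for a pseudo-replicated,
    study-shaped analysis; the aggregated wide table is the default unit
    of analysis.
    """
    if feature not in table.X.columns:
        raise ValueError(f"unknown feature {feature!r}")
    df = pd.DataFrame({"subject": table.subjects, "level": table.y,
                       "value": table.X[feature].to_numpy()})
    if per_cycle:
        return df
    wide = df.groupby(["subject", "level"])["value"].mean().unstack("level")
    if wide.isna().any().any() or wide.shape[1] != 3:
        raise ValueError("every subject needs a value in all three levels")
    return wide[[1, 2, 3]]


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float   # chi-square with k-1 df
    pvalue: float
    degenerate: bool = False


def friedman_test(table: pd.DataFrame) -> FriedmanResult:
    """Friedman rank test across the k=3 level columns.

    Values are ranked within each subject (average ranks on ties, no
    further tie correction); the statistic is
    ``12/(n k (k+1)) * sum(R_j^2) - 3 n (k+1)`` with a chi-square(k-1)
    reference. A table whose every row is constant is degenerate and
    reported as chi2=0, p=1 with a flag.
    """
    a = np.asarray(table, dtype=float)
    n, k = a.shape
    if n < 2 or k != 3:
        raise ValueError("need >= 2 subjects and exactly 3 conditions")
    ranks = np.vstack([rankdata(row) for row in a])
    if np.allclose(ranks.std(axis=1), 0.0):
        return FriedmanResult(0.0, 1.0, degenerate=True)
    R = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float(np.sum(R ** 2)) - 3.0 * n * (k + 1)
    p = float(chi2.sf(stat, k - 1))
    return FriedmanResult(float(stat), p)


@dataclass(frozen=True)
class PairwiseResult:
    pair: str
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool
    all_zero: bool = False


def wilcoxon_posthoc_bonferroni(table: pd.DataFrame,
                                alpha: float = ALPHA) -> list[PairwiseResult]:
    """Wilcoxon signed-rank tests for the three level pairs with Bonferroni
    adjustment (factor 3, capped at 1). Zero differences are dropped; a
    pair with only zero differences is flagged and non-significant. The
    exact null distribution is used up to n = 25 non-zero differences,
    the continuity-corrected normal approximation above."""
    a = np.asarray(table, dtype=float)
    if a.shape[0] < 5:
        raise ValueError("need n >= 5 subjects for the signed-rank test")
    out = []
    for i, j in PAIRS:
        d = a[:, i - 1] - a[:, j - 1]
        nz = d[d != 0]
        if nz.size == 0:
            out.append(PairwiseResult(PAIR_NAMES[(i, j)], 0.0, 1.0, 1.0,
                                      False, all_zero=True))
            continue
        method = "exact" if nz.size <= 25 else "approx"
        res = wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                       correction=(method == "approx"), method=method)
        p_adj = min(1.0, 3.0 * float(res.pvalue))
        out.append(PairwiseResult(PAIR_NAMES[(i, j)], float(res.statistic),
                                  float(res.pvalue), p_adj, p_adj < alpha))
    return out


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations over selected features with categorical
    strength labels."""

    r: pd.DataFrame
    categories: pd.DataFrame


def categorize_r(r: float) -> str:
    a = abs(r)
    if a >= 0.7:
        return "strong"
    if a >= 0.5:
        return "moderate"
    if a >= 0.3:
        return "low"
    return "negligible"


def pearson_categorize(X: pd.DataFrame) -> CorrelationReport:
    """Pearson r matrix over the columns of ``X`` plus strength categories.

    Raises on a constant column (undefined correlation), naming it.
    """
    if len(X) < 2:
        raise ValueError("need at least 2 rows")
    stds = X.std(axis=0)
    constant = list(stds.index[stds == 0])
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    r = X.corr(method="pearson")
    cats = r.apply(lambda col: col.map(categorize_r))
    return CorrelationReport(r=r, categories=cats)
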