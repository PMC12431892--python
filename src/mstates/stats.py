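"""Nonparametric group comparison of marker distributions.

Marker distributions across participants are typically skewed, so
between-group differences are tested with the Mann-Whitney U test
(pairwise, Bonferroni-corrected within each marker) and ordered trends
across the consciousness spectrum with a Spearman rank correlation
against the ordinal group coding.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "mann_whitney",
    "bonferroni",
    "spearman_trend",
    "GroupComparison",
    "TrendResult",
    "compare_groups",
    "DEFAULT_GROUP_ORDER",
]

DEFAULT_GROUP_ORDER = ["UWS", "MCS", "EMCS", "HC"]


@dataclass
class GroupComparison:
    marker: str
    group_a: str
    group_b: str
    U: float
    U_min: float
    p_raw: float
    p_bonferroni: float
    n1: int
    n2: int


@dataclass
class TrendResult:
    marker: str
    rs: float
    p: float
    group_coding: dict


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of the first sample, p).

    Uses the exact null distribution when the combined sample size is
    at most 20 and there are no ties, and the normal approximation with
    continuity and tie correction otherwise.  A pooled sample with no
    variation yields p = 1 (no evidence of a difference).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = sst.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, m * p)


def spearman_trend(values, groups, order: list | None = None,
                   marker: str = "") -> TrendResult:
    """Spearman correlation of a marker against ordinal group codes.

    ``order`` lists the groups from lowest to highest code; the default
    is the consciousness-spectrum ordering UWS < MCS < EMCS < HC.
    """
    values = np.asarray(values, dtype=float)
    groups = list(groups)
    if order is None:
        order = [g for g in DEFAULT_GROUP_ORDER if g in set(groups)]
        if not order:
            order = sorted(set(groups))
    coding = {g: i for i, g in enumerate(order)}
    unknown = set(groups) - set(coding)
    if unknown:
        raise ValueError(f"groups not in the ordering: {sorted(unknown)}")
    if len(set(groups)) < 2:
        raise ValueError("need at least 2 distinct groups for a trend")
    codes = np.array([coding[g] for g in groups], dtype=float)
    rs, p = sst.spearmanr(values, codes)
    return TrendResult(marker=marker, rs=float(rs), p=float(p),
                       group_coding=coding)


def compare_groups(table: pd.DataFrame, markers: list[str],
                   group_col: str = "group",
                   order: list | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Mann-Whitney tests plus the ordinal trend, per marker.

    The Bonferroni family is the set of pairwise comparisons of one
    marker (m = number of group pairs).  Returns two tidy frames:
    comparisons and trends.
    """
    group_names = (order if order is not None
                   else [g for g in DEFAULT_GROUP_ORDER
                         if g in set(table[group_col])]
                   or sorted(set(table[group_col])))
    pairs = list(combinations(group_names, 2))
    rows = []
    for marker in markers:
        raw = []
        for a, b in pairs:
            x = table.loc[table[group_col] == a, marker].to_numpy()
            y = table.loc[table[group_col] == b, marker].to_numpy()
            U, p = mann_whitney(x, y)
            raw.append((a, b, U, min(U, x.size * y.size - U), p,
                        x.size, y.size))
        adj = bonferroni([r[4] for r in raw], m=len(pairs))
        for (a, b, U, Umin, p, n1, n2), pb in zip(raw, adj):
            rows.append(GroupComparison(marker, a, b, U, Umin, p,
                                        float(pb), n1, n2))
    comparisons = pd.DataFrame([r.__dict__ for r in rows])
    trends = pd.DataFrame([
        spearman_trend(table[marker].to_numpy(),
                       table[group_col].tolist(),
                       order=group_names, marker=marker).__dict__
        for marker in markers
    ])
    return comparisons, trends
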