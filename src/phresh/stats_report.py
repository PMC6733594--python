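"""Group statistics and significance annotation.

The morphometry endpoints are compared between groups of per-embryo means
with the Mann-Whitney U test (exact p-values for small tie-free samples,
normal approximation with tie and continuity correction otherwise), and
annotated with the ** / *** star convention (p < 0.01, p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "star_annotation",
    "summarize_groups",
    "EXACT_N_LIMIT",
]

#: Exact enumeration is used whenever the pooled sample is this small
#: (and tie-free); beyond it the normal approximation is accurate.
EXACT_N_LIMIT = 16


@dataclass(frozen=True)
class GroupComparison:
    U: float
    p_two_sided: float
    method: str  # 'exact' or 'normal_approx'
    n1: int
    n2: int
    stars: str


def star_annotation(p: float, include_single_star: bool = False) -> str:
    """Significance stars: '***' iff p < 0.001, '**' iff 0.001 <= p < 0.01,
    else 'ns'.  ``include_single_star`` adds a '*' band for
    0.01 <= p < 0.05."""
    if not 0 < p <= 1:
        raise InvalidParameterError("p must lie in (0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if include_single_star and p < 0.05:
        return "*"
    return "ns"


def mann_whitney_u(a, b, alternative: str = "two-sided",
                   include_single_star: bool = False) -> GroupComparison:
    """Mann-Whitney U comparison of two samples of per-embryo values.

    For pooled samples of at most ``EXACT_N_LIMIT`` observations without
    ties the p-value is exact (full enumeration of rank arrangements);
    otherwise the normal approximation with continuity and mid-rank tie
    correction is used.  Two-sided p doubles the smaller tail, capped at 1.
    """
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (a.size + b.size) <= EXACT_N_LIMIT and not has_ties
    res = sps.mannwhitneyu(a, b, alternative=alternative,
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    p = float(min(1.0, res.pvalue))
    return GroupComparison(U=float(res.statistic), p_two_sided=p,
                           method="exact" if exact else "normal_approx",
                           n1=int(a.size), n2=int(b.size),
                           stars=star_annotation(p, include_single_star))


def summarize_groups(groups: dict[str, list[float]]) -> pd.DataFrame:
    """Mean ± SD table of per-embryo values by group.

    Sample standard deviation (n − 1 denominator); single-value groups
    report SD as missing.
    """
    rows = []
    for name, values in groups.items():
        v = np.asarray(list(values), float)
        if v.size == 0:
            raise InvalidParameterError(f"group {name!r} is empty")
        rows.append({
            "group": name,
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)
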