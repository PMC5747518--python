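"""Between-group nonparametric comparison machinery.

Mann-Whitney U (exact for small untied samples, normal approximation with
tie correction otherwise), the Hodges-Lehmann shift estimate with its
order-statistic confidence interval, and a group summary table.  All tests
are two-tailed; pairwise p values are reported unadjusted by default, with
an optional Holm correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "hodges_lehmann",
    "summarize_groups",
]

EXACT_MAX_N = 8


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    test: str
    statistic: float
    p_value: float
    hl_estimate: float
    hl_ci_low: float
    hl_ci_high: float

    def __post_init__(self) -> None:
        if not (self.hl_ci_low <= self.hl_estimate <= self.hl_ci_high):
            raise ValueError("Hodges-Lehmann CI does not bracket the estimate")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value outside [0, 1]")


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (for sample ``a``) and two-tailed p.

    Exact-enumeration p when ``min(n_a, n_b) <= 8`` and there are no ties;
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def hodges_lehmann(a, b, confidence: float = 0.95) -> tuple[float, float, float]:
    """Hodges-Lehmann shift estimate for a - b with its confidence interval.

    Estimate: median of all pairwise differences ``a_i - b_j``.  CI: the
    Mann-Whitney order-statistic inversion of the sorted difference list
    (normal-approximation critical rank).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    est = float(np.median(diffs))
    n, m = len(a), len(b)
    nm = n * m
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    # critical rank of the U statistic (Lehmann); clamp to valid range
    k = int(np.floor(nm / 2.0 - z * np.sqrt(nm * (n + m + 1) / 12.0)))
    k = max(k, 0)
    lo = diffs[k] if k < nm else diffs[0]
    hi = diffs[nm - 1 - k] if k < nm else diffs[-1]
    return est, float(lo), float(hi)


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def summarize_groups(
    values, labels, holm: bool = False
) -> list[GroupComparison]:
    """Pairwise group comparisons of a per-cell metric.

    ``values`` and ``labels`` are parallel sequences.  Every unordered
    group pair yields a :class:`GroupComparison`.  With ``holm=True`` the
    p values are Holm step-down adjusted (off by default to match
    unadjusted pairwise reporting).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels.tolist()))  # preserve order
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    by_group = {g: values[labels == g] for g in groups}
    comparisons: list[GroupComparison] = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            xa, xb = by_group[ga], by_group[gb]
            u, p = mann_whitney(xa, xb)
            est, lo, hi = hodges_lehmann(xa, xb)
            comparisons.append(
                GroupComparison(
                    group_a=str(ga),
                    group_b=str(gb),
                    n_a=len(xa),
                    n_b=len(xb),
                    mean_a=float(xa.mean()),
                    mean_b=float(xb.mean()),
                    sem_a=_sem(xa),
                    sem_b=_sem(xb),
                    test="mann-whitney",
                    statistic=u,
                    p_value=p,
                    hl_estimate=est,
                    hl_ci_low=lo,
                    hl_ci_high=hi,
                )
            )
    if holm and comparisons:
        ps = np.array([c.p_value for c in comparisons])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(running, 1.0)
        for c, p_adj in zip(comparisons, adj):
            c.p_value = float(p_adj)
    return comparisons
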