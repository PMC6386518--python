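"""Session- and group-level statistics.

The 2x2 contingency test is the closed-form Pearson chi-square without
continuity correction, ``n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))``, df = 1 —
the form that reproduces classic modulated/active-cell comparisons.
Group comparisons gate on Lilliefors normality: parametric
(t-test / one-way ANOVA) when every group passes, rank-based
(rank-sum / Kruskal-Wallis) otherwise, with Tukey-Kramer post-hoc
contrasts (on ranks in the non-parametric branch) for three or more
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["ContingencyTable2x2", "chi_square_2x2", "GroupCompareReport",
           "group_compare"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Returns ``(statistic, df, p)``; df is always 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("a zero marginal makes the test undefined")
    stat = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), 1, p


@dataclass
class GroupCompareReport:
    """Outcome of a normality-gated multi-group comparison."""

    test: str
    statistic: float
    p_value: float
    df: float | None
    normal: bool
    pairwise: list[tuple[int, int, bool]] = field(default_factory=list)
    # (group i, group j, significantly different at 0.05)


def _all_normal(groups: list[np.ndarray], alpha: float = 0.05) -> bool:
    for g in groups:
        if g.size < 4 or np.ptp(g) == 0:
            return False
        if lilliefors(g, dist="norm")[1] < alpha:
            return False
    return True


def group_compare(*groups, alpha: float = 0.05) -> GroupCompareReport:
    """Compare 2+ groups, choosing the test by a Lilliefors normality gate.

    Two groups: unpaired t-test if both pass normality, else Wilcoxon
    rank-sum.  Three or more: one-way ANOVA or Kruskal-Wallis, followed by
    Tukey-Kramer pairwise contrasts (computed on ranks when the
    non-parametric branch was taken).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size < 3:
            raise ValueError("each group needs at least 3 observations")
    normal = _all_normal(gs, alpha)

    if len(gs) == 2:
        if normal:
            res = sps.ttest_ind(gs[0], gs[1])
            return GroupCompareReport(
                "t-test", float(res.statistic), float(res.pvalue),
                float(gs[0].size + gs[1].size - 2), True,
            )
        res = sps.ranksums(gs[0], gs[1])
        return GroupCompareReport(
            "rank-sum", float(res.statistic), float(res.pvalue), None, False
        )

    if normal:
        stat, p = sps.f_oneway(*gs)
        values = np.concatenate(gs)
    else:
        stat, p = sps.kruskal(*gs)
        values = sps.rankdata(np.concatenate(gs))
    labels = np.concatenate([np.full(g.size, i) for i, g in enumerate(gs)])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = [
        (int(g1), int(g2), bool(rej))
        for g1, g2, rej in zip(
            tk.groupsunique[np.triu_indices(len(gs), 1)[0]],
            tk.groupsunique[np.triu_indices(len(gs), 1)[1]],
            tk.reject,
        )
    ]
    return GroupCompareReport(
        "anova" if normal else "kruskal-wallis",
        float(stat), float(p), float(len(gs) - 1), normal, pairs,
    )
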