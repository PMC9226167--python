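"""Two-group statistics: Fisher exact prevalence tests, Wilcoxon rank-sum
abundance tests, Benjamini-Hochberg adjustment, and an ingestion seam for
externally computed compositional differential-abundance (ANCOM-BC style)
result tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "prevalence_compare",
    "ancombc_adapter",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """present/absent counts for group1 (a, b) and group2 (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def margins(self) -> Tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def fisher_exact(table: ContingencyTable2x2, sided: str = "two") -> float:
    """Fisher's exact test p-value on a 2x2 table.

    The two-sided p is the probability-mass method: the sum of
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (with a small
    relative slack for floating-point ties).  Row margins of zero leave the
    test undefined.
    """
    row1, row2, _, _ = table.margins
    if row1 == 0 or row2 == 0:
        raise ValueError("zero row margin: test undefined")
    alternative = {"two": "two-sided", "less": "less", "greater": "greater"}[sided]
    _, p = stats.fisher_exact(table.as_array(), alternative=alternative)
    return float(min(p, 1.0))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], sided: str = "two"
) -> Tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when min(n, m) <= 25 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.  The
    switch point keeps small balanced designs (n = 24 per group) on the
    exact path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    alternative = {"two": "two-sided", "less": "less", "greater": "greater"}[sided]
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the sorted p-values.
    Idempotent and monotone in p-rank.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def prevalence_compare(
    presence: pd.DataFrame,
    groups: pd.Series,
    group_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-unit Fisher exact tests on presence/absence, BH-adjusted.

    ``presence`` is samples x units (boolean); ``groups`` assigns each
    sample to one of two groups.  Returns one row per unit with the 2x2
    counts, p, q, and the direction (which group has the higher prevalence
    fraction; empty string on a tie).
    """
    groups = groups.loc[presence.index]
    levels = list(group_order) if group_order is not None else sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    g1_mask = (groups == levels[0]).to_numpy()
    g2_mask = (groups == levels[1]).to_numpy()
    n1, n2 = int(g1_mask.sum()), int(g2_mask.sum())
    rows = []
    for unit in presence.columns:
        col = presence[unit].to_numpy(dtype=bool)
        a = int(col[g1_mask].sum())
        c = int(col[g2_mask].sum())
        table = ContingencyTable2x2(a, n1 - a, c, n2 - c)
        p = fisher_exact(table)
        frac1, frac2 = a / n1, c / n2
        direction = levels[0] if frac1 > frac2 else levels[1] if frac2 > frac1 else ""
        rows.append(
            {
                "unit": unit,
                "present_" + levels[0]: a,
                "absent_" + levels[0]: n1 - a,
                "present_" + levels[1]: c,
                "absent_" + levels[1]: n2 - c,
                "p": p,
                "direction": direction,
            }
        )
    out = pd.DataFrame(rows).set_index("unit")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


ANCOMBC_REQUIRED = ("unit", "lfc", "se", "q")


def ancombc_adapter(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and ingest an externally computed ANCOM-BC result table.

    The bias-corrected estimator itself is a published external method and
    is not recomputed here; this seam only checks shape (columns ``unit``,
    ``lfc``, ``se``, ``q``) and ranges, and returns a normalised frame with
    a ``direction`` column derived from the sign of the log-fold-change.
    """
    missing = [c for c in ANCOMBC_REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(
            f"malformed ANCOM-BC table: missing columns {missing}; "
            f"found {list(table.columns)}"
        )
    out = table.loc[:, list(ANCOMBC_REQUIRED)].copy()
    if out["unit"].duplicated().any():
        raise ValueError("malformed ANCOM-BC table: duplicated unit ids")
    q = out["q"].to_numpy(dtype=float)
    if np.isnan(q).any() or ((q < 0) | (q > 1)).any():
        raise ValueError("malformed ANCOM-BC table: q-values outside [0, 1]")
    if (out["se"].to_numpy(dtype=float) < 0).any():
        raise ValueError("malformed ANCOM-BC table: negative standard errors")
    out["direction"] = np.where(out["lfc"] > 0, "up", np.where(out["lfc"] < 0, "down", ""))
    return out.set_index("unit")
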