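"""Per-group descriptive summaries and omnibus group comparisons.

Descriptive summaries use the sample (n-1) standard deviation and linearly
interpolated quartiles.  Group comparisons are the one-way ANOVA F test
(explicit between/within sums of squares, F = MSB/MSW, upper-tail F
p-value) and the Kruskal-Wallis H test (midrank tie correction,
chi-squared approximation with k-1 degrees of freedom).  Post hoc
procedures (Tukey HSD, Dunn) are standard-library territory and are not
re-implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "OmnibusResult",
    "summarize",
    "summarize_table",
    "one_way_anova",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics of one treatment group for one metric."""

    label: str
    n: int
    mean: float
    std: float
    variance: float
    minimum: float
    q25: float
    median: float
    q75: float
    maximum: float
    degenerate: bool = False        # n == 1: spread undefined, reported as 0

    def as_dict(self) -> dict:
        return {
            "label": self.label, "n": self.n, "mean": self.mean,
            "std": self.std, "variance": self.variance,
            "minimum": self.minimum, "q25": self.q25, "median": self.median,
            "q75": self.q75, "maximum": self.maximum,
        }


@dataclass(frozen=True)
class OmnibusResult:
    """Result of an omnibus group-difference test."""

    test: str                       # "anova" | "kruskal_wallis"
    statistic: float                # F or H
    df: tuple[int, ...]             # (k-1, N-k) for ANOVA, (k-1,) for KW
    p_value: float


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    """Descriptive summary of one group of observations.

    Sample standard deviation (n-1 denominator); variance = std^2;
    quartiles by linear interpolation between order statistics.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    degenerate = x.size == 1
    std = 0.0 if degenerate else float(np.std(x, ddof=1))
    q25, med, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return GroupSummary(
        label=label,
        n=int(x.size),
        mean=float(x.mean()),
        std=std,
        variance=std**2,
        minimum=float(x.min()),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        maximum=float(x.max()),
        degenerate=degenerate,
    )


def summarize_table(
    table: pd.DataFrame, group_col: str, value_col: str
) -> pd.DataFrame:
    """Per-group summary rows of one metric column of a tidy table."""
    rows = [
        summarize(sub[value_col].to_numpy(), label=str(name)).as_dict()
        for name, sub in table.groupby(group_col, sort=True)
    ]
    return pd.DataFrame(rows)


def _check_groups(groups: Sequence[Sequence[float]], min_n: int) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < min_n for g in gs):
        raise ValueError(f"every group needs at least {min_n} observations")
    return gs


def one_way_anova(groups: Sequence[Sequence[float]]) -> OmnibusResult:
    """One-way ANOVA from explicit sums of squares.

    SSB = sum_g n_g (mean_g - grand)^2, SSW = sum_g sum (x - mean_g)^2,
    F = (SSB/(k-1)) / (SSW/(N-k)), p from the upper tail of F(k-1, N-k).
    """
    gs = _check_groups(groups, min_n=2)
    all_x = np.concatenate(gs)
    if np.ptp(all_x) == 0:
        raise ValueError("all observations identical: ANOVA is degenerate (0/0)")
    grand = all_x.mean()
    k, n = len(gs), all_x.size
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df = (k - 1, n - k)
    if ssw == 0:
        return OmnibusResult("anova", float("inf"), df, 0.0)
    f = (ssb / df[0]) / (ssw / df[1])
    p = float(sps.f.sf(f, df[0], df[1]))
    return OmnibusResult("anova", float(f), df, p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> OmnibusResult:
    """Kruskal-Wallis H with midrank tie correction.

    p from the chi-squared approximation with k-1 degrees of freedom.
    """
    gs = _check_groups(groups, min_n=1)
    if sum(g.size for g in gs) < 3:
        raise ValueError("Kruskal-Wallis needs at least 3 observations in total")
    if np.ptp(np.concatenate(gs)) == 0:
        raise ValueError("all observations identical: Kruskal-Wallis is degenerate")
    h, p = sps.kruskal(*gs)
    return OmnibusResult("kruskal_wallis", float(h), (len(gs) - 1,), float(p))
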