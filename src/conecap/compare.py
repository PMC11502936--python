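"""Cross-year change statistics.

Cone crops are compared between survey years at the transect level with a
two-sided Mann-Whitney rank-sum test (per-transect densities are skewed
counts, so a nonparametric test is appropriate). Carrying-capacity change
is summarised as a decline range over all cross-pairings of the before-
and after-interval bounds, which is the honest way to propagate interval
uncertainty through a percent change.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .survey_io import round_half_away

__all__ = [
    "RankSumMethod",
    "RankSumResult",
    "DeclineRange",
    "rank_sum_test",
    "fold_change",
    "decline_range",
]

# Exact null distribution is cheap up to this product of sample sizes.
EXACT_LIMIT = 400


class RankSumMethod(str, enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX = "normal_approx"


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Mann-Whitney test result.

    ``u_statistic`` is reported as min(U1, U2), the conventional tabulated
    form; the two one-sided statistics always satisfy U1 + U2 = n1*n2.
    """

    u_statistic: float
    n1: int
    n2: int
    p_value: float
    method: RankSumMethod

    def __post_init__(self) -> None:
        if not (0 <= self.u_statistic <= self.n1 * self.n2):
            raise ValueError("U must lie in [0, n1*n2]")
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class DeclineRange:
    """Percent decline interval between two estimate intervals."""

    min_percent: float
    max_percent: float

    def __post_init__(self) -> None:
        if self.min_percent > self.max_percent:
            raise ValueError("min_percent exceeds max_percent")

    def rounded(self) -> tuple[int, int]:
        return round_half_away(self.min_percent), round_half_away(self.max_percent)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Mann-Whitney U test on two samples of per-transect densities.

    Uses the exact null distribution when ``n1*n2 <= 400`` and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if n1 * n2 <= EXACT_LIMIT and not has_ties:
        method = RankSumMethod.EXACT
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = RankSumMethod.NORMAL_APPROX
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    u1 = float(res.statistic)
    u = min(u1, n1 * n2 - u1)
    return RankSumResult(
        u_statistic=u,
        n1=n1,
        n2=n2,
        p_value=min(float(res.pvalue), 1.0),
        method=method,
    )


def fold_change(before: float, after: float) -> float:
    """Multiplicative change ``after / before``."""
    if before <= 0:
        raise ValueError("baseline value must be positive")
    return after / before


def decline_range(
    before_interval: tuple[float, float], after_interval: tuple[float, float]
) -> DeclineRange:
    """Percent-decline range between two (low, high) estimate intervals.

    Every cross-pairing of a before-bound b with an after-bound a yields a
    candidate decline 100*(1 - a/b); the result spans the minimum and
    maximum of the four candidates.
    """
    b_low, b_high = before_interval
    a_low, a_high = after_interval
    for name, (low, high) in (("before", before_interval), ("after", after_interval)):
        if low <= 0 or high <= 0:
            raise ValueError(f"{name} interval bounds must be positive")
        if low > high:
            raise ValueError(f"{name} interval has low > high")
    declines = [100.0 * (1.0 - a / b) for b in (b_low, b_high) for a in (a_low, a_high)]
    return DeclineRange(min_percent=min(declines), max_percent=max(declines))
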