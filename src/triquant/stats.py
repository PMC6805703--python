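"""Group comparison and correlation with explicit parametric gating.

Small stroke cohorts rarely justify parametric tests, so every comparison
is routed through an explicit gate and the routing is reported alongside
the result: Welch's t-test (with Cohen's d) only when both groups pass a
Lilliefors-corrected Kolmogorov-Smirnov normality check at alpha and both
have at least eight observations, otherwise the two-sided Mann-Whitney U
(with the rank-biserial correlation).  Correlations use Pearson only for
normal variables with n > 30, otherwise Spearman.  Whether the data live
on an interval scale cannot be inferred from numbers and is the caller's
assertion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = ["GroupComparison", "CorrelationResult", "compare_groups", "correlate"]

_MIN_PARAMETRIC_N = 8


@dataclass(frozen=True)
class GroupComparison:
    test_name: str  # "t-test" | "mann-whitney"
    statistic: float
    p_value: float
    effect_size: float
    effect_size_name: str  # "cohen_d" | "rank_biserial_r"
    group_summaries: dict
    rationale: str
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


class CorrelationResult(NamedTuple):
    coefficient: float
    p_value: float
    method: str  # "pearson" | "spearman"


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    """Lilliefors-style K-S test against a normal with fitted parameters."""
    if np.ptp(x) == 0:
        return False
    return lilliefors(x, dist="norm")[1] > alpha


def _summary(x: np.ndarray) -> dict:
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sem": float(sps.sem(x)) if x.size > 1 else 0.0,
    }


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare two independent groups, choosing the test by the gate above."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")

    big_enough = a.size >= _MIN_PARAMETRIC_N and b.size >= _MIN_PARAMETRIC_N
    if big_enough and _is_normal(a, alpha) and _is_normal(b, alpha):
        res = sps.ttest_ind(a, b, equal_var=False)
        pooled = np.sqrt(
            ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
            / (a.size + b.size - 2)
        )
        d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
        return GroupComparison(
            test_name="t-test",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            effect_size=d,
            effect_size_name="cohen_d",
            group_summaries={"a": _summary(a), "b": _summary(b)},
            rationale=(
                f"both groups normal (Lilliefors p > {alpha}) and n >= "
                f"{_MIN_PARAMETRIC_N}: Welch t-test"
            ),
            alpha=alpha,
        )

    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    u = float(res.statistic)  # U of group a
    r = 2.0 * u / (a.size * b.size) - 1.0  # rank-biserial, + when a larger
    reason = (
        "group too small for parametric treatment"
        if not big_enough
        else f"normality rejected (Lilliefors p <= {alpha})"
    )
    return GroupComparison(
        test_name="mann-whitney",
        statistic=u,
        p_value=float(res.pvalue),
        effect_size=float(r),
        effect_size_name="rank_biserial_r",
        group_summaries={"a": _summary(a), "b": _summary(b)},
        rationale=f"{reason}: two-sided Mann-Whitney U",
        alpha=alpha,
    )


def correlate(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> CorrelationResult:
    """Pearson for normal variables with n > 30, Spearman otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    if x.size > 30 and _is_normal(x, alpha) and _is_normal(y, alpha):
        res = sps.pearsonr(x, y)
        return CorrelationResult(float(res.statistic), float(res.pvalue), "pearson")
    res = sps.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), "spearman")
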