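"""Two-sample comparison of per-animal efficiency indices.

The reference procedure is the classical (pooled-variance) Student
unpaired t-test, two-sided, applied to per-animal means with n = animals.
Both a raw-values entry point and a summary-statistics entry point are
provided; on identical sufficient statistics they agree to floating
precision.  A Welch option exists for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "StatsError", "t_test_values", "t_test_summary"]

# reported when the pooled variance is exactly zero but the means differ:
# the t statistic diverges and the p-value underflows past any float
P_UNDERFLOW_FLOOR = 1e-300


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_two_sided: float
    welch: bool = False
    notes: tuple[str, ...] = ()

    def __str__(self) -> str:  # compact mean +/- SD report
        return (
            f"{self.group_a} ({self.mean_a:.3g} ± {self.sd_a:.3g}, "
            f"n={self.n_a}) vs {self.group_b} ({self.mean_b:.3g} ± "
            f"{self.sd_b:.3g}, n={self.n_b}): t={self.t_statistic:.3f}, "
            f"df={self.degrees_of_freedom:g}, p={self.p_two_sided:.4g}"
        )


def _from_stats(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    group_a: str, group_b: str, welch: bool,
) -> GroupComparison:
    if n_a < 2 or n_b < 2:
        raise StatsError("each group needs at least 2 observations")
    if sd_a < 0 or sd_b < 0:
        raise StatsError("standard deviations must be >= 0")

    notes: list[str] = []
    if sd_a == 0.0 and sd_b == 0.0:
        df = float(n_a + n_b - 2)
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            t = np.inf if mean_a > mean_b else -np.inf
            p = P_UNDERFLOW_FLOOR
            notes.append("zero pooled variance with unequal means; p floored")
    else:
        t, p = sps.ttest_ind_from_stats(
            mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=not welch)
        if welch:
            va, vb = sd_a**2 / n_a, sd_b**2 / n_b
            df = (va + vb) ** 2 / (
                va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        else:
            df = float(n_a + n_b - 2)
    return GroupComparison(
        group_a=group_a, group_b=group_b, n_a=n_a, n_b=n_b,
        mean_a=float(mean_a), mean_b=float(mean_b),
        sd_a=float(sd_a), sd_b=float(sd_b),
        t_statistic=float(t), degrees_of_freedom=float(df),
        p_two_sided=float(p), welch=welch, notes=tuple(notes),
    )


def t_test_values(
    values_a, values_b,
    group_a: str = "A", group_b: str = "B",
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-sided t-test on raw per-animal values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 observations")
    return _from_stats(
        a.mean(), float(np.std(a, ddof=1)), a.size,
        b.mean(), float(np.std(b, ddof=1)), b.size,
        group_a, group_b, welch)


def t_test_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    group_a: str = "A", group_b: str = "B",
    welch: bool = False,
) -> GroupComparison:
    """Same test from published sufficient statistics (mean, SD, n)."""
    return _from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                       group_a, group_b, welch)
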