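"""Simple group statistics reported by the pipeline.

Per-bee summaries are compared with one-sample t-tests (PI against zero)
and Welch two-sample t-tests (reinforced vs unreinforced); percent change
summarizes first-to-last trial shifts.  Mixed-effects trajectories (bee as
random effect) are deliberately out of scope — the pipeline reports
per-bee summaries instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "percent_change",
    "proportion_pct",
    "one_sample_t",
    "two_sample_t",
]


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    df: float
    p_value: float
    test_kind: str  # one_sample | two_sample
    degenerate: bool = False


def percent_change(v0: float, v1: float) -> float:
    """100 · (v1 − v0) / v0 — sign preserved (reductions are negative)."""
    if v0 == 0:
        raise ZeroDivisionError("percent change undefined for a zero baseline")
    return 100.0 * (v1 - v0) / v0


def proportion_pct(k: int, n: int) -> float:
    """A count as a percentage of a total (e.g. excluded bees per cohort)."""
    if n <= 0:
        raise ZeroDivisionError("proportion undefined for an empty cohort")
    return 100.0 * k / n


def _sem(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def one_sample_t(values, mu0: float = 0.0, label: str = "sample") -> GroupComparison:
    """Two-sided one-sample t-test of the mean against ``mu0``."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("one-sample t-test needs n >= 2")
    degenerate = bool(np.allclose(values, values[0]))
    if degenerate:
        t, p = np.nan, np.nan
    else:
        t, p = sps.ttest_1samp(values, mu0)
    return GroupComparison(
        group_a=label,
        group_b=f"mu0={mu0}",
        n_a=len(values),
        n_b=0,
        mean_a=float(values.mean()),
        mean_b=mu0,
        sem_a=_sem(values),
        sem_b=np.nan,
        t_statistic=float(t),
        df=float(len(values) - 1),
        p_value=float(p),
        test_kind="one_sample",
        degenerate=degenerate,
    )


def two_sample_t(
    values_a, values_b, label_a: str = "a", label_b: str = "b"
) -> GroupComparison:
    """Welch two-sample t-test (unequal variances, Welch–Satterthwaite df)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two-sample t-test needs n >= 2 per group")
    degenerate = bool(np.allclose(a, a[0]) and np.allclose(b, b[0]))
    if degenerate and np.isclose(a[0], b[0]):
        t, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=_sem(a),
        sem_b=_sem(b),
        t_statistic=float(t),
        df=df,
        p_value=float(p),
        test_kind="two_sample",
        degenerate=degenerate,
    )
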