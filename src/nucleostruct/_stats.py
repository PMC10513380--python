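"""Small shared statistics: two-sample t tests, one-way ANOVA, t-based CIs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison summary (classical Student's t test by default)."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    label: str = ""
    welch: bool = False


def two_sample_t(a, b, *, welch: bool = False, label: str = "") -> GroupComparison:
    """Two-sided two-sample t test on raw values.

    Pooled-variance ("Student's") by default; Welch behind the flag.
    Requires n >= 2 per group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2 for a t test")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        n_a=int(a.size),
        n_b=int(b.size),
        t_statistic=float(t),
        p_value=float(p),
        label=label,
        welch=welch,
    )


def one_way_anova(groups: dict[str, list[float]] | list[list[float]]):
    """One-way ANOVA across >= 2 groups; returns (F, p)."""
    if isinstance(groups, dict):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def t_confidence_interval(values, confidence: float = 0.95):
    """Mean and t-based CI half-width; NaN half-width when n < 2 (flagged upstream)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n == 0:
        return np.nan, np.nan, 0
    m = float(v.mean())
    if n < 2:
        return m, np.nan, n
    se = float(v.std(ddof=1) / np.sqrt(n))
    tq = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
    return m, tq * se, n
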