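"""Paired cohort comparison of plan metrics: mean±SD, t-tests, parity ratios.

All plan variants in a comparison are generated on the same patients'
anatomy, so the default test is the paired two-sided Student's t-test on
per-subject differences (an unpaired variant is available).  Significance is
declared at p <= alpha (default 0.05) with no multiple-testing correction —
each metric is reported per-comparison, which is a documented limitation.

The parity ratio of two plans is the ratio of cohort means, mean(b)/mean(a),
with plan ``a`` the "former" (denominator) plan: a ratio < 1 means the former
plan achieved the lower (better, for an OAR) value.  A mean-of-ratios
estimator is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AlignmentError

__all__ = [
    "PairedComparison",
    "summarize",
    "paired_t_test",
    "parity_ratio",
    "comparison_table",
]


@dataclass(frozen=True)
class PairedComparison:
    """One metric compared between plan variants a and b across subjects."""

    metric: str
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_ratio_b_over_a: float
    t_stat: float
    p_value: float
    significant: bool
    degenerate: bool = False


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator; 0 for a single value)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty vector")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return mean, sd


def paired_t_test(
    a,
    b,
    alpha: float = 0.05,
    metric: str = "",
    paired: bool = True,
) -> PairedComparison:
    """Two-sided Student's t-test between subject-aligned metric vectors.

    Paired (default): t = mean(d) / (sd(d)/sqrt(n)) on differences d = a - b,
    with n-1 degrees of freedom.  All-zero differences are a degenerate
    result (t = 0, p = 1, flagged), not an exception — identical plans are a
    legitimate comparison outcome.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"a and b must be 1-d and subject-aligned, got {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError(f"need at least 2 subjects for a t-test, got {n}")
    mean_a, sd_a = summarize(a)
    mean_b, sd_b = summarize(b)
    ratio = mean_b / mean_a if mean_a != 0 else float("nan")

    degenerate = False
    if paired:
        d = a - b
        sd_d = d.std(ddof=1)
        if sd_d == 0.0:
            t_stat, p = 0.0, 1.0
            degenerate = True
            if d[0] != 0.0:
                # constant non-zero difference: infinitely significant in the
                # model's terms; report as such rather than p = 1
                t_stat = np.inf if d[0] > 0 else -np.inf
                p = 0.0
        else:
            t_stat = float(d.mean() / (sd_d / np.sqrt(n)))
            p = float(2.0 * sps.t.sf(abs(t_stat), df=n - 1))
    else:
        if sd_a == 0.0 and sd_b == 0.0:
            t_stat, p = 0.0, 1.0
            degenerate = True
        else:
            t_stat, p = sps.ttest_ind(a, b)
            t_stat, p = float(t_stat), float(p)
    return PairedComparison(
        metric=metric,
        n=n,
        mean_a=mean_a,
        sd_a=sd_a,
        mean_b=mean_b,
        sd_b=sd_b,
        mean_ratio_b_over_a=ratio,
        t_stat=t_stat,
        p_value=p,
        significant=bool(p <= alpha),
        degenerate=degenerate,
    )


def parity_ratio(a, b, estimator: str = "ratio-of-means") -> float:
    """Parity ratio mean(b)/mean(a); ``a`` is the former (denominator) plan.

    ``estimator='mean-of-ratios'`` averages per-subject ratios instead
    (subjects with a zero denominator value are excluded from that average).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parity ratio requires subject-aligned vectors")
    if estimator == "ratio-of-means":
        denom = a.mean()
        if denom == 0:
            return float("nan")
        return float(b.mean() / denom)
    if estimator == "mean-of-ratios":
        ok = a != 0
        if not ok.any():
            return float("nan")
        return float((b[ok] / a[ok]).mean())
    raise ValueError(f"unknown estimator {estimator!r}")


def comparison_table(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    alpha: float = 0.05,
    paired: bool = True,
) -> pd.DataFrame:
    """Per-metric paired comparison of two subject-indexed metric tables.

    Both inputs are DataFrames indexed by subject id with one column per
    metric (e.g. ``Bladder_Dmax``).  Rows must align subject-for-subject;
    a mismatch raises :class:`AlignmentError` naming the missing subjects.

    Returns one row per metric with mean±SD for each variant, the parity
    ratio (b over a), t statistic, p-value, and a significance mark ('*' when
    p <= alpha, following the one-mark-per-comparison table convention).
    """
    missing_in_b = sorted(set(metrics_a.index) - set(metrics_b.index))
    missing_in_a = sorted(set(metrics_b.index) - set(metrics_a.index))
    if missing_in_a or missing_in_b:
        parts = []
        if missing_in_b:
            parts.append(f"missing from b: {missing_in_b}")
        if missing_in_a:
            parts.append(f"missing from a: {missing_in_a}")
        raise AlignmentError("subject mismatch — " + "; ".join(parts))
    metrics_b = metrics_b.loc[metrics_a.index]

    shared = [c for c in metrics_a.columns if c in metrics_b.columns]
    rows = []
    for col in shared:
        a = metrics_a[col].to_numpy(dtype=float)
        b = metrics_b[col].to_numpy(dtype=float)
        if a.size < 2:
            # a single subject admits no test: report summaries and the
            # ratio, flag the row degenerate
            cmp = PairedComparison(
                metric=col, n=a.size,
                mean_a=float(a.mean()), sd_a=0.0,
                mean_b=float(b.mean()), sd_b=0.0,
                mean_ratio_b_over_a=float(b.mean() / a.mean()) if a.mean() != 0 else float("nan"),
                t_stat=float("nan"), p_value=float("nan"),
                significant=False, degenerate=True,
            )
        else:
            cmp = paired_t_test(a, b, alpha=alpha, metric=col, paired=paired)
        rows.append(
            {
                "metric": col,
                "n": cmp.n,
                "mean_a": cmp.mean_a,
                "sd_a": cmp.sd_a,
                "mean_b": cmp.mean_b,
                "sd_b": cmp.sd_b,
                "ratio_b_over_a": parity_ratio(a, b),
                "t_stat": cmp.t_stat,
                "p_value": cmp.p_value,
                "significant": cmp.significant,
                "degenerate": cmp.degenerate,
                "mark": "*" if cmp.significant and not cmp.degenerate else "",
            }
        )
    return pd.DataFrame(rows)
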