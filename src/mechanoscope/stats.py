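"""Group comparisons and summaries for regional modulus measurements.

Each independent spheroid contributes one regional mean; groups (cell line x
hydrogel x region) are compared with a two-sample t-test (pooled-variance
Student by default, Welch behind a flag) and summarized with boxplot
five-number summaries whose whiskers are the min and max.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSample:
    """Per-spheroid modulus means (kPa) for one condition."""

    values: tuple
    group_id: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("group values must be finite")
        object.__setattr__(self, "values", tuple(vals))

    @property
    def n(self) -> int:
        return len(self.values)


def significance_tier(p: float) -> str:
    """Threshold map: p < 0.001 -> ***, < 0.01 -> **, < 0.05 -> *, else ns."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class TestResult:
    t: float
    df: float
    p: float
    tier: str
    degenerate: bool = False


def two_sample_ttest(a: GroupSample, b: GroupSample, welch: bool = False) -> TestResult:
    """Two-sided two-sample t-test on independent group means.

    Pooled-variance Student's t with ``n_a + n_b - 2`` degrees of freedom by
    default; ``welch=True`` uses the Welch-Satterthwaite correction instead.
    Zero pooled variance is handled without exceptions: equal means give
    t = 0, p = 1; unequal means give p = 0 flagged degenerate.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs n >= 2")
    x, y = np.asarray(a.values), np.asarray(b.values)
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return TestResult(t=0.0, df=a.n + b.n - 2, p=1.0, tier="ns")
        return TestResult(
            t=np.inf if x.mean() > y.mean() else -np.inf,
            df=a.n + b.n - 2, p=0.0, tier="***", degenerate=True,
        )
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    t, p = float(res.statistic), float(res.pvalue)
    return TestResult(t=t, df=df, p=p, tier=significance_tier(p))


def boxplot_summary(values: Sequence[float]) -> dict:
    """Median, quartiles (linear-interpolation convention), min/max whiskers."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    return {
        "median": float(np.median(vals)),
        "q25": float(np.quantile(vals, 0.25)),  # linear interpolation
        "q75": float(np.quantile(vals, 0.75)),
        "whisker_low": float(vals.min()),
        "whisker_high": float(vals.max()),
        "quantile_convention": "linear",
    }


def build_comparison_table(region_stats: pd.DataFrame, group_cols=("cell_line", "hydrogel")) -> pd.DataFrame:
    """Across-spheroid mean +/- SD per (condition x region) cell.

    Input: one row per (spheroid, region) with a ``mean_kPa`` column plus the
    grouping columns. Per-spheroid means are first-class: the table reports
    the mean and sample SD across spheroids, not pooled voxels. Empty cells
    produce a blank entry.
    """
    group_cols = [c for c in group_cols if c in region_stats.columns]
    keys = group_cols + ["region"]
    rows = []
    for key, sub in region_stats.groupby(keys, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        vals = sub["mean_kPa"].to_numpy(dtype=float)
        rows.append(
            dict(zip(keys, key))
            | {
                "mean_kPa": float(vals.mean()),
                "sd_kPa": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n_spheroids": int(vals.size),
                "cell": f"{vals.mean():.4g} ± {vals.std(ddof=1):.3g}" if vals.size > 1 else f"{vals.mean():.4g}",
            }
        )
    return pd.DataFrame(rows)
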