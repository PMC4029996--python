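"""Length summaries for mined elements: internal-region computation,
single-pass 3-SD outlier filtering per subgroup, and LTR-vs-element
length correlation."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def internal_length(element_length: float, ltr_length: float) -> float:
    """Internal coding region: element length minus twice the LTR length."""
    return element_length - 2.0 * ltr_length


def add_internal_lengths(table: pd.DataFrame) -> pd.DataFrame:
    """Annotate a length table with internal lengths and validity flags.

    Rows whose internal length is non-positive are flagged invalid and
    should be excluded downstream.
    """
    out = table.copy()
    out["internal_length"] = internal_length(out["element_length"],
                                             out["ltr_length"])
    out["valid"] = out["internal_length"] > 0
    return out


def filter_outliers(table: pd.DataFrame, k: float = 3.0,
                    group_col: str = "subgroup",
                    value_col: str = "ltr_length"
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows more than k sample SDs from their subgroup mean.

    Single pass: means and SDs are computed once on the input, never
    re-computed on the filtered table.  Returns (kept, removed).
    """
    keep_mask = pd.Series(True, index=table.index)
    for _, idx in table.groupby(group_col).groups.items():
        values = table.loc[idx, value_col].astype(float)
        if len(values) < 2:
            warnings.warn("subgroup with fewer than 2 records passed through")
            continue
        mean, sd = values.mean(), values.std(ddof=1)
        keep_mask.loc[idx] = (values - mean).abs() <= k * sd
    return table[keep_mask].copy(), table[~keep_mask].copy()


def correlate(x, y) -> tuple[float, float, float]:
    """OLS fit of y on x; returns (slope, intercept, R^2).

    R^2 is the squared Pearson correlation, as a spreadsheet trendline
    reports it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def subgroup_summary(table: pd.DataFrame, group_col: str = "subgroup",
                     value_col: str = "ltr_length") -> pd.DataFrame:
    """Per-subgroup mean and sample SD of LTR length (summary-table shape)."""
    grouped = table.groupby(group_col)[value_col]
    return pd.DataFrame({
        "n": grouped.size(),
        "mean": grouped.mean().round(1),
        "sd": grouped.std(ddof=1).round(1),
    }).reset_index()
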