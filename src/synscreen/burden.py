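"""Longitudinal in-vivo tumour-burden summaries.

A burden table records the percentage of labelled (e.g. mCherry-positive)
leukemia cells among blood cells per mouse and sampling day. Fold changes are
per-mouse ratios to the baseline day; group summaries report the arithmetic
mean and sample SD of the percentages and the geometric mean of the per-mouse
fold changes (fold changes are ratio-scaled, so the geometric mean is the
appropriate central tendency).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["validate_burden_table", "fold_changes", "summarize_groups"]

_COLUMNS = {"mouse", "group", "day", "percent"}


def validate_burden_table(table: pd.DataFrame, baseline_day=None) -> pd.DataFrame:
    if not _COLUMNS.issubset(table.columns):
        raise ValueError(f"burden table needs columns {sorted(_COLUMNS)}")
    if table.duplicated(["mouse", "day"]).any():
        raise ValueError("duplicate (mouse, day) records")
    if ((table["percent"] < 0) | (table["percent"] > 100)).any():
        raise ValueError("percent values must lie in [0, 100]")
    if baseline_day is not None:
        have_baseline = table[table["day"] == baseline_day]["mouse"]
        missing = set(table["mouse"]) - set(have_baseline)
        if missing:
            raise ValueError(f"mice without baseline day {baseline_day}: {sorted(missing)}")
    return table


def fold_changes(table: pd.DataFrame, baseline_day=0) -> pd.DataFrame:
    """Per-mouse fold change versus baseline at each later day.

    FC = percent(day) / percent(baseline). Mice with a zero baseline have no
    defined fold change and are excluded with a warning.
    """
    table = validate_burden_table(table, baseline_day)
    base = table[table["day"] == baseline_day].set_index("mouse")["percent"]
    zero = base.index[base == 0]
    if len(zero):
        warnings.warn(f"excluding mice with zero baseline: {sorted(zero)}", stacklevel=2)
    later = table[table["day"] != baseline_day].copy()
    later = later[~later["mouse"].isin(zero)]
    later["fold_change"] = later["percent"].to_numpy() / later["mouse"].map(base).to_numpy()
    return later[["mouse", "group", "day", "fold_change"]].reset_index(drop=True)


def summarize_groups(table: pd.DataFrame, baseline_day=0) -> pd.DataFrame:
    """Per-group, per-day burden summary.

    Columns: mean and sample SD (n-1 denominator; absent for n = 1) of the
    percentages, group size n, and the geometric mean of per-mouse fold
    changes versus baseline (NaN on the baseline day itself).
    """
    table = validate_burden_table(table, baseline_day)
    fcs = fold_changes(table, baseline_day)
    gm = fcs.groupby(["group", "day"])["fold_change"].apply(
        lambda v: float(np.exp(np.mean(np.log(v))))
    )
    out = (
        table.groupby(["group", "day"])["percent"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan, n="size")
        .reset_index()
    )
    out["fold_change"] = [
        gm.get((g, d), np.nan) for g, d in zip(out["group"], out["day"])
    ]
    return out
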