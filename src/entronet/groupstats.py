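"""Paired before/after group statistics over the long-format metric table.

The core comparison is a paired-sample Student's t-test, applied per metric
and per mean-degree level to the (after - before) differences across
subjects; the null hypothesis is that the paired differences are normally
distributed with zero mean.  Significance is flagged exactly as reported
tables do: "bold" for 0.005 <= p < 0.05 and "*" for p < 0.005.  No
multiple-testing correction is applied across grid levels; per-level
p-values are reported with flags only.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BEFORE",
    "AFTER",
    "make_metric_table",
    "validate_metric_table",
    "significance_flag",
    "paired_comparison_by_level",
    "zero_mean_test",
    "behavioral_correlation",
    "subject_summary",
]

BEFORE = "before"
AFTER = "after"
CONDITIONS = (BEFORE, AFTER)

#: quartile rule used throughout (median-unbiased order-statistic interpolation)
QUANTILE_METHOD = "median_unbiased"

TABLE_COLUMNS = ["subject", "condition", "level", "metric", "value"]


def make_metric_table(rows: Iterable[Tuple[str, str, int, str, float]]) -> pd.DataFrame:
    """Long-format table: one row per (subject, condition, level, metric)."""
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    validate_metric_table(df)
    return df


def validate_metric_table(table: pd.DataFrame) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metric table lacks columns {missing}")
    bad_cond = set(table["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions {sorted(bad_cond)}; expected {CONDITIONS}")
    dup = table.duplicated(subset=["subject", "condition", "level", "metric"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject, condition, level, metric) rows at index {list(table.index[dup])[:5]}"
        )


def significance_flag(p: float) -> str:
    """'' / 'bold' / '*' exactly as printed tables mark p-values."""
    if not np.isfinite(p):
        return ""
    if p < 0.005:
        return "*"
    if p < 0.05:
        return "bold"
    return ""


def _paired_t(diffs: np.ndarray) -> Tuple[float, float, str]:
    """One-sample t of differences against zero, with degenerate handling.

    All-zero differences give (t=0, p=1); nonzero constant differences have
    undefined t (zero variance) and are reported missing with a note.
    """
    n = diffs.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    if not np.isfinite(diffs).all():
        return math_nan, math_nan, "non-finite differences"
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        if np.all(diffs == 0.0):
            return 0.0, 1.0, ""
        return math_nan, math_nan, "zero-variance differences"
    t = diffs.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), ""


math_nan = float("nan")


def paired_comparison_by_level(
    table: pd.DataFrame, metric: str, strict: bool = True
) -> pd.DataFrame:
    """Per-level paired t-test of (after - before) for one metric.

    Returns a frame indexed by level with the condition means/SDs, the t
    statistic, the two-sided p-value (df = n_subjects - 1), the printed-style
    flag, and a note for degenerate cases.  With ``strict=False``, levels
    with fewer than two complete (before, after) pairs are skipped instead
    of raising — useful for derived quantities (e.g. null-normalized ratios)
    that are undefined on some networks.
    """
    validate_metric_table(table)
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} not present in the table")
    wide = sub.pivot_table(
        index=["level", "subject"], columns="condition", values="value", aggfunc="first"
    )
    for cond in (BEFORE, AFTER):
        if cond not in wide.columns:
            wide[cond] = np.nan
    records = []
    for level, grp in wide.groupby(level="level"):
        grp = grp.dropna(subset=[BEFORE, AFTER])
        if len(grp) < 2:
            if strict:
                raise ValueError(
                    f"level {level}: need >= 2 subjects with both conditions, got {len(grp)}"
                )
            continue
        before = grp[BEFORE].to_numpy(float)
        after = grp[AFTER].to_numpy(float)
        with np.errstate(invalid="ignore"):
            diffs = after - before
        t, p, note = _paired_t(diffs)
        records.append(
            {
                "level": level,
                "n_subjects": len(grp),
                "mean_before": before.mean(),
                "sd_before": before.std(ddof=1),
                "mean_after": after.mean(),
                "sd_after": after.std(ddof=1),
                "t_stat": t,
                "p_value": p,
                "flag": significance_flag(p),
                "note": note,
            }
        )
    return pd.DataFrame.from_records(records).set_index("level")


def zero_mean_test(diffs: Sequence[float]) -> Tuple[float, float]:
    """One-sample two-sided t-test of the values against a zero mean."""
    d = np.asarray(diffs, dtype=float)
    t, p, note = _paired_t(d)
    if note:
        warnings.warn(note, stacklevel=2)
    return t, p


def behavioral_correlation(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Pearson r between per-subject values, with a two-sided p (df = n - 2).

    Used e.g. to relate per-subject entropy changes to psychometric score
    changes (CADSS/BPRS deltas) or head-motion (frame displacement) deltas.
    Zero variance in either input yields (nan, nan) with a warning.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must be paired by subject (equal length)")
    if xa.size < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    if xa.std() == 0 or ya.std() == 0:
        warnings.warn("zero variance input; correlation undefined", stacklevel=2)
        return math_nan, math_nan
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


def subject_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary (min, Q1, median, Q3, max) per subject, condition
    and metric, over the grid levels.  Quartiles use median-unbiased
    order-statistic interpolation."""
    validate_metric_table(table)

    def _summary(vals: pd.Series) -> pd.Series:
        v = vals.to_numpy(float)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
        return pd.Series(
            {"min": v.min(), "q1": q1, "median": med, "q3": q3, "max": v.max()}
        )

    out = (
        table.groupby(["subject", "condition", "metric"])["value"]
        .apply(_summary)
        .unstack()
    )
    return out
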