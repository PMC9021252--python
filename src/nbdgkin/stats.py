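"""Preprocessing arithmetic and population summary statistics.

Covers the arithmetic applied to fluorescence values extracted from images
(background subtraction, size normalization) and the summaries reported for
clonal populations: coefficient of variation, Pearson correlation, Welch's
unpaired two-tailed t-test, steady-state means with SEM, and the
percent-of-baseline ratio convention used to compare conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model import CellTrace

__all__ = [
    "background_subtract",
    "normalize_by_size",
    "coefficient_of_variation",
    "pearson_r",
    "welch_t",
    "percent_of_baseline",
    "steady_state_mean",
    "summary_table",
]


def background_subtract(cell_values, bg_values) -> tuple[np.ndarray, bool]:
    """Element-wise background subtraction.

    Returns (corrected, has_negative).  Negative corrected values are kept —
    clipping at zero would bias low-signal means upward — but flagged so
    callers can report them.
    """
    cell = np.asarray(cell_values, dtype=float)
    bg = np.asarray(bg_values, dtype=float)
    if cell.shape != bg.shape:
        raise ValueError(
            f"length mismatch: cell has {cell.shape}, background has {bg.shape}"
        )
    corrected = cell - bg
    return corrected, bool(np.any(corrected < 0))


def normalize_by_size(total_fluor: float, size) -> float:
    """Mean fluorescence per unit size (pixels or area)."""
    if not size > 0:
        raise ValueError(f"size must be > 0, got {size}")
    return total_fluor / size


def coefficient_of_variation(values) -> float:
    """CV as a percentage: 100 * sample SD (n-1 denominator) / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def welch_t(x, y) -> tuple[float, float, float]:
    """Unpaired two-tailed Welch's t-test.

    Returns (t, df, p) with Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch's t-test needs n >= 2 in both samples")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("Welch's t-test undefined for two degenerate samples")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def percent_of_baseline(mean_baseline: float, mean_new: float) -> float:
    """New mean as a percentage of the baseline mean: 100 * new / old.

    This ratio convention is the only arithmetic consistent with the reported
    condition pairs (740 -> 1072 a.u. reported as 145%, 1072 -> 1714 a.u. as
    160%), even though those comparisons are worded as "increases".
    """
    if not mean_baseline > 0:
        raise ValueError("baseline mean must be > 0")
    return 100.0 * mean_new / mean_baseline


def steady_state_mean(
    traces: list[CellTrace], t_query: float = 900.0
) -> tuple[float, float, int]:
    """Across-cell mean and SEM of per-cell fluorescence at ``t_query``.

    Each cell contributes its sample nearest to ``t_query``; a cell with no
    sample within half its median frame interval of ``t_query`` is an error
    (the steady state was not observed).  Returns (mean, SEM, n).
    """
    if not traces:
        raise ValueError("no traces given")
    vals = []
    for tr in traces:
        idx = int(np.argmin(np.abs(tr.times - t_query)))
        dt = float(np.median(np.diff(tr.times)))
        if abs(tr.times[idx] - t_query) > dt / 2.0:
            raise ValueError(
                f"cell {tr.cell_id}: no sample within {dt / 2.0:g} s of t={t_query:g}"
            )
        vals.append(tr.values[idx])
    arr = np.asarray(vals)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), sem, int(arr.size)


def summary_table(
    traces: list[CellTrace],
    t_query: float = 900.0,
    log_params: np.ndarray | None = None,
    condition: str = "condition",
):
    """One-row condition summary as a DataFrame: n cells, steady-state
    mean +/- SEM, CV (%), and — when per-cell (ln u, ln d) estimates are
    given — the Pearson correlation between them with its p-value."""
    import pandas as pd

    mean, sem, n = steady_state_mean(traces, t_query)
    vals = []
    for tr in traces:
        idx = int(np.argmin(np.abs(tr.times - t_query)))
        vals.append(tr.values[idx])
    row = {
        "condition": condition,
        "n_cells": n,
        "steady_state_mean_au": mean,
        "steady_state_sem_au": sem,
        "cv_percent": coefficient_of_variation(vals),
    }
    if log_params is not None:
        lp = np.asarray(log_params, dtype=float).reshape(-1, 2)
        r, p = pearson_r(lp[:, 0], lp[:, 1])
        row["pearson_r_logu_logd"] = r
        row["pearson_p"] = p
    return pd.DataFrame([row])
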