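"""Daily surveillance signals from classified post streams.

A classified stream becomes a date-indexed series (count of relevant posts
per day, or the proportion of that day's posts that are relevant), smoothed
with a moving average to damp day-of-week effects, and compared against a
reference health-indicator series (e.g. daily out-of-hours GP or tele-health
call proportions) with a Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .learners import RELEVANT

logger = logging.getLogger(__name__)

#: A signal series is a pandas Series of finite values indexed by
#: consecutive calendar dates (DatetimeIndex, daily frequency).
SignalSeries = pd.Series


def daily_signal(
    timestamps: Sequence[datetime],
    labels: Sequence[str],
    mode: str = "proportion",
    positive: str = RELEVANT,
) -> SignalSeries:
    """Aggregate classified posts into a gap-free daily series.

    ``count`` mode: relevant posts per date.  ``proportion`` mode: relevant
    posts divided by all posts that date; dates with no posts at all get 0
    (with a warning in proportion mode, where the ratio is undefined).
    """
    if mode not in ("proportion", "count"):
        raise ValueError(f"unknown mode: {mode}")
    if len(timestamps) != len(labels):
        raise ValueError("timestamps and labels must have equal length")
    if not timestamps:
        return pd.Series(dtype=float)

    df = pd.DataFrame(
        {
            "date": pd.to_datetime([t.date() for t in timestamps]),
            "relevant": [int(l == positive) for l in labels],
        }
    )
    grouped = df.groupby("date")["relevant"].agg(["sum", "count"])
    full_index = pd.date_range(grouped.index.min(), grouped.index.max(), freq="D")
    grouped = grouped.reindex(full_index, fill_value=0)
    if mode == "count":
        values = grouped["sum"].astype(float)
    else:
        empty = grouped["count"] == 0
        if empty.any():
            logger.warning(
                "%d dates have no posts; proportion undefined, reported as 0", int(empty.sum())
            )
        values = (grouped["sum"] / grouped["count"].replace(0, np.nan)).fillna(0.0)
    values.name = mode
    return values


def moving_average(s: SignalSeries, window: int = 7, mode: str = "trailing") -> SignalSeries:
    """Moving-average smoothing.

    Trailing mode (default): value at day d is the mean of days d-window+1
    ... d; the first window-1 values average the days available so far.
    Centred mode mirrors that behaviour around d.  Output length equals
    input length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(s):
        raise ValueError("window longer than the series")
    centred = {"trailing": False, "centred": True, "centered": True}[mode]
    return s.rolling(window, min_periods=1, center=centred).mean()


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    degenerate: bool = False


def correlate(a: SignalSeries, b: SignalSeries) -> CorrelationResult:
    """Pearson correlation on the date-intersected values of two series,
    with a two-sided p-value.  Zero variance in either series is degenerate
    (r undefined)."""
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping dates")
    x = a.loc[common].to_numpy(dtype=float)
    y = b.loc[common].to_numpy(dtype=float)
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        logger.warning("correlation degenerate: a series has zero variance")
        return CorrelationResult(float("nan"), float("nan"), len(common), degenerate=True)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(common))


def load_reference_series(path: str | Path) -> SignalSeries:
    """Read a two-column (ISO date, value) CSV into a SignalSeries."""
    df = pd.read_csv(path)
    date_col, value_col = df.columns[:2]
    s = pd.Series(
        df[value_col].to_numpy(dtype=float),
        index=pd.to_datetime(df[date_col]),
        name=value_col,
    )
    return s.sort_index()


def save_series(s: SignalSeries, path: str | Path, value_name: str = "value") -> None:
    out = pd.DataFrame({"date": s.index.strftime("%Y-%m-%d"), value_name: s.to_numpy()})
    out.to_csv(path, index=False)
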