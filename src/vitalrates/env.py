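"""Environmental covariates: growing degree-days, interval mean temperature,
rainfall-maxima percentiles.

Temperature and rainfall series are daily pandas Series/DataFrames with a
``date`` column and a ``value`` column (degC for temperature, mm for rainfall).
Missing days are excluded from sums and means, never imputed; each result
reports how many days in the requested window were actually available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _as_series(series: pd.DataFrame | pd.Series) -> pd.Series:
    """Normalize input to a float Series indexed by normalized datetime."""
    if isinstance(series, pd.DataFrame):
        if not {"date", "value"}.issubset(series.columns):
            raise ValueError("environmental table needs 'date' and 'value' columns")
        s = pd.Series(
            np.asarray(series["value"], dtype=float),
            index=pd.to_datetime(series["date"]),
        )
    else:
        s = series.astype(float)
        s.index = pd.to_datetime(s.index)
    s = s[~s.index.duplicated(keep="first")].sort_index()
    return s


@dataclass
class GDDResult:
    """Accumulated growing degree-days over a calendar window."""

    label: str
    gdd: float
    base_temp: float
    n_days_used: int
    n_days_missing: int


def compute_gdd(
    series: pd.DataFrame | pd.Series,
    window: tuple[str, str],
    base_temp: float = 0.0,
    label: str | None = None,
) -> GDDResult:
    """Growing degree-days: sum of ``max(T_d - base_temp, 0)`` over the window.

    ``window`` is an inclusive (start, end) pair of dates. Days absent from the
    series are counted as missing, not interpolated. Raises ``ValueError`` when
    the series does not cover a single day of the window.
    """
    s = _as_series(series)
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if end < start:
        raise ValueError(f"window end {end.date()} before start {start.date()}")
    n_window = (end - start).days + 1
    sub = s.loc[start:end]
    if sub.empty:
        raise ValueError(
            f"temperature series has no coverage of window {start.date()}..{end.date()}"
        )
    gdd = float(np.maximum(sub.to_numpy() - base_temp, 0.0).sum())
    return GDDResult(
        label=label or f"{start.date()}..{end.date()}",
        gdd=gdd,
        base_temp=base_temp,
        n_days_used=int(sub.size),
        n_days_missing=int(n_window - sub.size),
    )


def mean_interval_temperature(
    series: pd.DataFrame | pd.Series, start, end
) -> tuple[float, float]:
    """Arithmetic mean of daily temperature over ``[start, end)``.

    Returns ``(mean, fraction_missing)``. Used as the interval covariate
    ``T-bar`` in the survival models. Raises on zero coverage.
    """
    s = _as_series(series)
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if not start < end:
        raise ValueError("interval start must precede end")
    sub = s.loc[start : end - pd.Timedelta(days=1)]
    n_window = (end - start).days
    if sub.empty:
        raise ValueError(f"no temperature coverage in [{start.date()}, {end.date()})")
    return float(sub.mean()), float(1.0 - sub.size / n_window)


def maxima_percentile(annual_maxima, value: float) -> float:
    """Empirical percentile rank of ``value`` within a sample of annual maxima.

    Nearest-rank convention: ``100 * (# maxima <= value) / n``. The sample
    maximum therefore sits at the 100th percentile and any value below the
    sample minimum at the 0th.
    """
    x = np.asarray(annual_maxima, dtype=float)
    if x.size == 0:
        raise ValueError("empty maxima sample")
    if x.size < 2:
        raise ValueError("need at least 2 annual maxima for a percentile rank")
    return float(100.0 * np.count_nonzero(x <= value) / x.size)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, ``100 * sd / mean``."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean
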