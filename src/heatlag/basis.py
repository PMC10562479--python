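"""Natural cubic spline bases and the exposure-lag cross-basis.

The cross-basis is the tensor product of a natural cubic basis over exposure
values (knots equally spaced over the observed range) and a natural cubic
basis over lag days 0..max_lag (knots equally spaced on a log(lag + 1)
scale, so lag 0 is admissible).  Row t of the cross-basis depends only on
exposures at days t, t-1, ..., t-max_lag of the same season; lags reaching
before a season start are padded with the season's first observed value,
mirroring the convention of the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["natural_cubic_basis", "equal_range_knots", "log_lag_knots",
           "lag_basis_matrix", "trend_spline", "CrossBasis", "build_crossbasis"]


def natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (no intercept column).

    For K knots (boundaries included) returns K-1 columns: the identity
    ramp plus K-2 truncated-power terms constrained to be linear beyond the
    boundary knots.
    """
    x = np.asarray(x, dtype=float)
    k = np.sort(np.asarray(knots, dtype=float))
    if len(k) < 3:
        raise ValueError("natural cubic basis needs at least 3 knots")
    if len(np.unique(k)) != len(k):
        raise ValueError("knots must be distinct")

    def d(i: int) -> np.ndarray:
        return (np.clip(x - k[i], 0.0, None) ** 3 - np.clip(x - k[-1], 0.0, None) ** 3) / (
            k[-1] - k[i]
        )

    d_last = d(len(k) - 2)
    cols = [x] + [d(i) - d_last for i in range(len(k) - 2)]
    return np.column_stack(cols)


def equal_range_knots(values: np.ndarray, df: int) -> np.ndarray:
    """df+1 knots equally spaced over the observed range (df basis columns)."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi <= lo:
        raise ValueError("cannot place knots on a constant series")
    return np.linspace(lo, hi, df + 1)


def log_lag_knots(max_lag: int, df: int) -> np.ndarray:
    """df knots equally spaced on the log(lag + 1) scale over [0, max_lag].

    The lag margin includes the intercept, so a natural spline on df knots
    spans exactly df functions (the constant plus df-1 spline terms).
    """
    return np.exp(np.linspace(np.log(1.0), np.log(max_lag + 1.0), df)) - 1.0


def lag_basis_matrix(lags: np.ndarray, lag_knots: np.ndarray) -> np.ndarray:
    """Natural cubic lag basis with intercept, knots log-spaced in lag.

    A natural cubic spline on K knots spans a K-dimensional space including
    the constant; with K = 2 (boundary knots only, the df = 2 case) that
    space degenerates to {1, lag}, so the log spacing of interior knots
    matters only for df >= 3.
    """
    t = np.asarray(lags, dtype=float)
    k = np.asarray(lag_knots, dtype=float)
    ones = np.ones_like(t)
    if len(k) < 2:
        return ones[:, None]
    if len(k) == 2:
        return np.column_stack([ones, t])
    return np.column_stack([ones, natural_cubic_basis(t, k)])


def _quantile_knots(values: np.ndarray, df: int) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, df + 1)
    k = np.quantile(values, qs)
    return np.unique(k)


def trend_spline(day_index: np.ndarray, df: int) -> np.ndarray:
    """Long-term-trend natural spline on the calendar day index.

    Knots at equal quantiles of the in-sample index, so season gaps are
    spanned smoothly.  The index is rescaled to [0, 1] before the basis is
    built; this leaves the spanned function space unchanged but keeps the
    cubic terms well conditioned over multi-year spans.
    """
    t = np.asarray(day_index, dtype=float)
    span = np.ptp(t)
    if span == 0:
        raise ValueError("trend spline needs more than one distinct date")
    t = (t - t.min()) / span
    knots = _quantile_knots(t, df)
    if len(knots) < 3:
        raise ValueError("too few distinct dates for the requested trend df")
    return natural_cubic_basis(t, knots)


@dataclass
class CrossBasis:
    """Tensor-product exposure-lag basis and the metadata to reuse it."""

    matrix: np.ndarray
    var_knots: np.ndarray
    lag_knots: np.ndarray
    max_lag: int
    var_df: int
    lag_df: int
    exposure: np.ndarray = field(repr=False)
    dates: pd.DatetimeIndex = field(repr=False)

    @property
    def n_columns(self) -> int:
        return self.var_df * self.lag_df

    def var_basis(self, x: np.ndarray) -> np.ndarray:
        return natural_cubic_basis(np.asarray(x, dtype=float), self.var_knots)

    def lag_basis(self, lags: np.ndarray) -> np.ndarray:
        return lag_basis_matrix(np.asarray(lags, dtype=float), self.lag_knots)


def build_crossbasis(
    values: np.ndarray | pd.Series,
    dates: pd.DatetimeIndex | pd.Series,
    max_lag: int = 14,
    var_df: int = 2,
    lag_df: int = 2,
    var_knots: np.ndarray | None = None,
) -> CrossBasis:
    """Build the exposure-lag cross-basis for a seasonally gapped daily series."""
    values = np.asarray(values, dtype=float)
    dates = pd.DatetimeIndex(pd.to_datetime(dates))
    if len(values) != len(dates):
        raise ValueError("values and dates must align")
    if len(values) < max_lag + 1:
        raise ValueError(f"need at least {max_lag + 1} rows to build a {max_lag}-lag basis")

    if var_knots is None:
        if np.ptp(values) == 0.0:  # constant series: any knot placement works
            var_knots = values[0] + np.linspace(-1.0, 1.0, var_df + 1)
        else:
            var_knots = equal_range_knots(values, var_df)
    lag_knots = log_lag_knots(max_lag, lag_df)

    lags = np.arange(max_lag + 1, dtype=float)
    lag_b = lag_basis_matrix(lags, lag_knots)             # (L+1, lag_df)

    # lagged exposure matrix Q[t, l] = x_{t-l}, season-padded
    years = dates.year.to_numpy()
    q = np.empty((len(values), max_lag + 1))
    for year in np.unique(years):
        mask = years == year
        x = values[mask]
        padded = np.concatenate([np.full(max_lag, x[0]), x])
        for l in range(max_lag + 1):
            q[mask, l] = padded[max_lag - l : max_lag - l + len(x)]

    v = natural_cubic_basis(q.ravel(), var_knots).reshape(len(values), max_lag + 1, var_df)
    matrix = np.einsum("tlj,lk->tjk", v, lag_b).reshape(len(values), var_df * lag_df)
    return CrossBasis(
        matrix=matrix,
        var_knots=np.asarray(var_knots, dtype=float),
        lag_knots=lag_knots,
        max_lag=max_lag,
        var_df=var_df,
        lag_df=lag_df,
        exposure=values,
        dates=dates,
    )
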