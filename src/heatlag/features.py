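"""Daily relative risk (DRR) and the lag-specified weather feature table.

DRR normalises each day's death count by the mean daily count of the same
year's July–August season, so every season averages to exactly 1 and
year-to-year drift (aging, medical progress) is removed before modelling.

The feature table follows the convention: for each weather element E with a
lag specification of N days it contains the same-day value ``E``, the lagged
levels ``EPre2 .. EPreN`` and lagged differences ``EDiffPre1 .. EDiffPreN``
(value today minus the value n days before), plus the accumulated high
temperature ``AcTmax30``, rainfall ``Rain`` and day-of-week ``DOW``.

``AcTmax30`` is the running within-season sum of daily-maximum-temperature
exceedances above 30 degC:  AcTmax30_t = sum_{i <= t, same season} max(Tmax_i - 30, 0).
It resets at each season start and is nondecreasing within a season.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LagSpec",
    "compute_drr",
    "compute_actmax30",
    "build_feature_table",
    "feature_count",
    "ELEMENT_COLUMNS",
]

# feature-name prefix -> weather-table column
ELEMENT_COLUMNS = {"Tmax": "tmax", "Vap": "vap", "Pres": "pres"}

ACTMAX_THRESHOLD = 30.0


@dataclass
class LagSpec:
    """Lag days per weather element, as specified by the DLNM lag analysis."""

    tmax: int = 8
    vap: int = 9
    pres: int = 14

    def __post_init__(self) -> None:
        for name in ("tmax", "vap", "pres"):
            v = int(getattr(self, name))
            if not 1 <= v <= 14:
                raise ValueError(f"lag for {name} must lie in [1, 14], got {v}")
            setattr(self, name, v)

    def lag_for(self, prefix: str) -> int:
        return int(getattr(self, ELEMENT_COLUMNS[prefix]))

    @property
    def max_lag(self) -> int:
        return max(self.tmax, self.vap, self.pres)

    def to_dict(self) -> dict[str, int]:
        return {"tmax": self.tmax, "vap": self.vap, "pres": self.pres}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LagSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


def compute_drr(mortality: pd.DataFrame) -> pd.DataFrame:
    """Daily relative risk: count / same-year in-season mean count.

    Raises a normalisation error naming the year if any season has zero
    total deaths.
    """
    dates = pd.to_datetime(mortality["date"])
    counts = mortality["count"].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("death counts must be nonnegative")
    years = dates.dt.year
    means = pd.Series(counts).groupby(years.to_numpy()).transform("mean").to_numpy()
    zero_years = sorted(set(years[means == 0.0]))
    if zero_years:
        raise ValueError(
            f"cannot normalise DRR: season(s) {zero_years} have zero total deaths"
        )
    return pd.DataFrame({"date": dates.to_numpy(), "drr": counts / means})


def compute_actmax30(weather: pd.DataFrame, threshold: float = ACTMAX_THRESHOLD) -> pd.Series:
    """Within-season accumulated temperature exceedance (degC-days)."""
    dates = pd.to_datetime(weather["date"])
    exceed = np.clip(weather["tmax"].to_numpy(dtype=float) - threshold, 0.0, None)
    acc = pd.Series(exceed).groupby(dates.dt.year.to_numpy()).cumsum()
    acc.name = "AcTmax30"
    acc.index = weather.index
    return acc


def feature_count(lagspec: LagSpec, diff_mode: str = "full") -> int:
    """Number of columns the feature table will contain (excluding date).

    ``full``: per element 1 level + (N-1) lagged levels + N differences;
    ``first``: per element 1 level + (N-1) lagged levels + 1 first difference.
    Plus AcTmax30, Rain and DOW.
    """
    total = 0
    for prefix in ELEMENT_COLUMNS:
        n = lagspec.lag_for(prefix)
        n_diff = n if diff_mode == "full" else 1
        total += 1 + (n - 1) + n_diff
    return total + 3  # AcTmax30, Rain, DOW


def build_feature_table(
    weather: pd.DataFrame, lagspec: LagSpec, diff_mode: str = "full"
) -> pd.DataFrame:
    """Build the lag-specified feature table for one city.

    All lagging is performed within seasons, so no feature for day t ever
    uses data after t or from another year.  The first ``max_lag`` in-season
    days of each year lack full same-season history and are dropped.
    """
    if diff_mode not in ("full", "first"):
        raise ValueError("diff_mode must be 'full' or 'first'")
    dates = pd.to_datetime(weather["date"])
    years = dates.dt.year.to_numpy()
    season_len = int(pd.Series(years).value_counts().min())
    if lagspec.max_lag >= season_len:
        raise ValueError(
            f"maximum lag {lagspec.max_lag} does not fit in a {season_len}-day season"
        )

    cols: dict[str, pd.Series] = {}
    for prefix, column in ELEMENT_COLUMNS.items():
        series = weather[column].astype(float)
        grouped = series.groupby(years)
        n = lagspec.lag_for(prefix)
        cols[prefix] = series
        for lag in range(2, n + 1):
            cols[f"{prefix}Pre{lag}"] = grouped.shift(lag)
        diff_lags = range(1, n + 1) if diff_mode == "full" else (1,)
        for lag in diff_lags:
            cols[f"{prefix}DiffPre{lag}"] = series - grouped.shift(lag)
        if prefix == "Tmax":
            cols["AcTmax30"] = compute_actmax30(weather)
    cols["Rain"] = weather["rain"].astype(float)
    cols["DOW"] = pd.Series(
        pd.Categorical(dates.dt.day_name(), categories=list(_DOW_ORDER)),
        index=weather.index,
    )

    out = pd.DataFrame(cols, index=weather.index)
    out.insert(0, "date", dates.to_numpy())
    # drop rows lacking full same-season history
    day_rank = out.groupby(years).cumcount()
    out = out.loc[day_rank >= lagspec.max_lag].reset_index(drop=True)
    return out


_DOW_ORDER = (
    "Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday",
)


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    f = features.copy()
    f["date"] = pd.to_datetime(f["date"]).dt.strftime("%Y-%m-%d")
    f.to_csv(path, index=False, float_format="%.6f")
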