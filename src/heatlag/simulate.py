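"""Seeded synthetic two-city weather and mortality generator.

Weather is generated per city and season (July–August) as a seasonal mean
curve plus AR(1) noise for the daily maximum temperature, vapor pressure
coupled affinely to temperature, an independent AR(1) air-pressure series and
zero-inflated rainfall.  Daily death counts are Poisson with a log-linear
rate combining a lag-distributed hinge effect of temperature above a
threshold with an accumulated-heat (acclimatisation) term.  Every draw is
determined by ``(config.seed, city, year)``, so extending the record does not
perturb earlier years.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import SEASON_LENGTH, ScenarioConfig

__all__ = [
    "GroundTruth",
    "generate_weather",
    "generate_mortality",
    "generate_future_weather",
    "season_dates",
    "write_weather",
    "write_mortality",
]

# stream tags keep the per-(city, year) substreams for weather, mortality and
# future-noise draws disjoint
_STREAM_WEATHER = 1
_STREAM_MORTALITY = 2
_STREAM_FUTURE = 3


def _city_key(city: str) -> int:
    return zlib.crc32(str(city).encode()) & 0x7FFFFFFF


def _rng(seed: int, city: str, year_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _city_key(city), year_index, stream])


def season_dates(start_year: int, n_years: int) -> pd.DatetimeIndex:
    """All July 1 – August 31 dates for ``n_years`` consecutive years."""
    parts = [
        pd.date_range(f"{start_year + i}-07-01", f"{start_year + i}-08-31", freq="D")
        for i in range(n_years)
    ]
    return pd.DatetimeIndex(np.concatenate([p.values for p in parts]))


def _seasonal_mean(config: ScenarioConfig, offset: float) -> np.ndarray:
    d = np.arange(SEASON_LENGTH, dtype=float)
    return (
        config.tmax_mean
        + offset
        + config.seasonal_amplitude * np.sin(np.pi * d / (SEASON_LENGTH - 1))
    )


def _ar1(rng: np.random.Generator, n: int, coeff: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise of marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    innov_sd = sd * np.sqrt(1.0 - coeff**2)
    e[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        e[t] = coeff * e[t - 1] + shocks[t - 1]
    return e


def generate_weather(config: ScenarioConfig, city: str) -> pd.DataFrame:
    """Generate one city's in-season daily weather table.

    Returns a frame with columns ``date, tmax, vap, pres, rain`` (one row per
    July–August day), with the city name stored in ``frame.attrs['city']``.
    """
    config.validate()
    if city not in config.city_offsets:
        raise ValueError(
            f"unknown city {city!r}; configured cities: {sorted(config.city_offsets)}"
        )
    offset = float(config.city_offsets[city])
    mean_curve = _seasonal_mean(config, offset)

    frames = []
    for i in range(config.n_years):
        rng = _rng(config.seed, city, i, _STREAM_WEATHER)
        tmax = mean_curve + _ar1(rng, SEASON_LENGTH, config.ar1_coeff, config.tmax_sd)
        vap = (
            config.vap_intercept
            + config.vap_coupling * tmax
            + rng.normal(0.0, config.vap_noise_sd, SEASON_LENGTH)
        )
        pres = config.pres_mean + _ar1(rng, SEASON_LENGTH, config.pres_ar1, config.pres_sd)
        wet = rng.random(SEASON_LENGTH) >= config.rain_zero_prob
        rain = np.where(wet, rng.exponential(config.rain_scale, SEASON_LENGTH), 0.0)
        year = config.start_year + i
        dates = pd.date_range(f"{year}-07-01", f"{year}-08-31", freq="D")
        frames.append(
            pd.DataFrame({"date": dates, "tmax": tmax, "vap": vap, "pres": pres, "rain": rain})
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["city"] = city
    return out


@dataclass
class GroundTruth:
    """Record of the effect parameters used to generate one mortality series."""

    city: str
    baseline_deaths: float
    effect_threshold: float
    effect_slope: float
    lag_weights: tuple[float, ...]
    acclim_coeff: float
    acclim_cap: float
    seed: int

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["lag_weights"] = list(self.lag_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GroundTruth":
        d = dict(d)
        d["lag_weights"] = tuple(d["lag_weights"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _lagged_exceedance(tmax: np.ndarray, threshold: float, weights: np.ndarray) -> np.ndarray:
    """Lag-weighted hinge exceedance for one season.

    Lags reaching before the season start are padded with the season's first
    observed value, so the output covers every in-season day.
    """
    n_lag = len(weights)
    padded = np.concatenate([np.full(n_lag - 1, tmax[0]), tmax]) if n_lag > 1 else tmax
    exceed = np.clip(padded - threshold, 0.0, None)
    out = np.zeros(len(tmax))
    for l, w in enumerate(weights):
        if w == 0.0:
            continue
        out += w * exceed[n_lag - 1 - l : n_lag - 1 - l + len(tmax)]
    return out


def generate_mortality(
    weather: pd.DataFrame, config: ScenarioConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw Poisson daily death counts driven by the weather table.

    log mean = log(baseline) + slope * sum_l w_l * max(Tmax_{t-l} - threshold, 0)
             + acclim * min(AcTmax30_t, acclim_cap)
    """
    config.validate()
    city = weather.attrs.get("city", "target")
    weights = np.asarray(config.lag_weights)
    counts = []
    dates = pd.to_datetime(weather["date"])
    years = dates.dt.year.to_numpy()
    for i, year in enumerate(np.unique(years)):
        tmax = weather.loc[years == year, "tmax"].to_numpy()
        if len(tmax) < len(weights):
            raise ValueError(
                f"season {year} has {len(tmax)} days, shorter than the "
                f"{len(weights)}-day lag window"
            )
        lagged = _lagged_exceedance(tmax, config.effect_threshold, weights)
        actmax = np.cumsum(np.clip(tmax - 30.0, 0.0, None))
        log_mu = (
            np.log(config.baseline_deaths)
            + config.effect_slope * lagged
            + config.acclim_coeff * np.minimum(actmax, config.acclim_cap)
        )
        rng = _rng(config.seed, city, i, _STREAM_MORTALITY)
        counts.append(rng.poisson(np.exp(log_mu)))
    out = pd.DataFrame({"date": dates.to_numpy(), "count": np.concatenate(counts)})
    out.attrs["city"] = city
    truth = GroundTruth(
        city=city,
        baseline_deaths=config.baseline_deaths,
        effect_threshold=config.effect_threshold,
        effect_slope=config.effect_slope,
        lag_weights=tuple(config.lag_weights),
        acclim_coeff=config.acclim_coeff,
        acclim_cap=config.acclim_cap,
        seed=config.seed,
    )
    return out, truth


def generate_future_weather(
    weather: pd.DataFrame,
    config: ScenarioConfig,
    warming_offset: float,
    seed: int | None = None,
    noise_sd: float | None = None,
    year_shift: int = 36,
) -> pd.DataFrame:
    """Shift a present-era weather table into a warmed future window.

    Tmax is shifted by ``warming_offset`` degC plus fresh AR(1) noise; vapor
    pressure is re-derived through the temperature coupling; air pressure and
    rainfall are carried over; dates are relabelled ``year_shift`` years later.
    """
    config.validate()
    city = weather.attrs.get("city", "target")
    seed = config.seed if seed is None else int(seed)
    noise_sd = config.future_noise_sd if noise_sd is None else float(noise_sd)

    out = weather.copy()
    dates = pd.to_datetime(out["date"])
    years = dates.dt.year.to_numpy()
    noise = np.empty(len(out))
    for i, year in enumerate(np.unique(years)):
        mask = years == year
        rng = _rng(seed, city, i, _STREAM_FUTURE)
        noise[mask] = _ar1(rng, int(mask.sum()), config.ar1_coeff, noise_sd)
    delta = warming_offset + noise
    out["tmax"] = out["tmax"].to_numpy() + delta
    out["vap"] = out["vap"].to_numpy() + config.vap_coupling * delta
    out["date"] = dates + pd.DateOffset(years=year_shift)
    out.attrs["city"] = city
    return out


def write_weather(weather: pd.DataFrame, path: str | Path) -> None:
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"]).dt.strftime("%Y-%m-%d")
    w.to_csv(path, index=False, float_format="%.6f")


def write_mortality(mortality: pd.DataFrame, path: str | Path) -> None:
    m = mortality.copy()
    m["date"] = pd.to_datetime(m["date"]).dt.strftime("%Y-%m-%d")
    m.to_csv(path, index=False)
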