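"""Scenario and pipeline configuration objects.

The :class:`ScenarioConfig` pins down the synthetic study conditions: an
11-year July–August record for two cities, one of which runs systematically
hotter, with daily death counts driven by a lag-distributed heat effect above
a temperature threshold plus an accumulated-heat acclimatisation term.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

SEASON_START = (7, 1)   # July 1
SEASON_END = (8, 31)    # August 31
SEASON_LENGTH = 62      # days per July–August season


def _default_city_offsets() -> dict[str, float]:
    # source city ~1 degC hotter at the 50th/95th percentiles than the target
    return {"target": 0.0, "source": 1.0}


def _default_lag_weights() -> tuple[float, ...]:
    # front-loaded heat-effect profile over lags 0..7: largest same-day,
    # decaying over about one week, as lag-response analyses of summer
    # cardiovascular mortality typically estimate
    w = 0.6 ** np.arange(8)
    return tuple(w / w.sum())


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic two-city weather/mortality scenario.

    Temperatures are degC, vapor/air pressures hPa, rainfall mm, death
    counts expected deaths per day.  ``effect_slope`` is log relative risk
    per degC of lag-weighted exceedance above ``effect_threshold``;
    ``acclim_coeff`` is log relative risk per degC-day of accumulated
    exceedance (negative values emulate heat acclimatisation), saturating
    once the accumulation reaches ``acclim_cap`` degC-days, since
    physiological adaptation to heat load levels off.
    """

    n_years: int = 11
    start_year: int = 2009
    city_offsets: dict[str, float] = field(default_factory=_default_city_offsets)
    ar1_coeff: float = 0.6
    tmax_mean: float = 31.0
    tmax_sd: float = 2.2
    seasonal_amplitude: float = 1.5
    vap_intercept: float = 6.0
    vap_coupling: float = 0.65
    vap_noise_sd: float = 1.2
    pres_mean: float = 1009.0
    pres_sd: float = 3.0
    pres_ar1: float = 0.7
    rain_zero_prob: float = 0.65
    rain_scale: float = 8.0
    baseline_deaths: float = 10.0
    effect_threshold: float = 30.0
    effect_slope: float = 0.08
    lag_weights: tuple[float, ...] = field(default_factory=_default_lag_weights)
    acclim_coeff: float = -0.001
    acclim_cap: float = 130.0
    future_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.lag_weights = tuple(float(w) for w in self.lag_weights)
        self.validate()

    def validate(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ValueError("ar1_coeff must lie in [0, 1)")
        if not 0.0 <= self.pres_ar1 < 1.0:
            raise ValueError("pres_ar1 must lie in [0, 1)")
        for name in ("tmax_sd", "vap_noise_sd", "pres_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.rain_zero_prob <= 1.0:
            raise ValueError("rain_zero_prob must lie in [0, 1]")
        if self.baseline_deaths <= 0:
            raise ValueError("baseline_deaths must be > 0")
        w = np.asarray(self.lag_weights, dtype=float)
        if w.size == 0 or np.any(w < 0):
            raise ValueError("lag_weights must be nonnegative and non-empty")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("lag_weights must sum to 1 within 1e-9")
        if not self.city_offsets:
            raise ValueError("city_offsets must name at least one city")

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["lag_weights"] = list(self.lag_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end analysis pipeline.

    ``scenario_offsets`` map warming-level names to degC shifts applied to
    the present-era daily maximum temperature; the defaults emulate low /
    middle / high warming tendencies of three climate models under a
    high-emissions pathway.
    """

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    target_city: str = "target"
    source_city: str = "source"
    # DLNM settings
    max_lag: int = 14
    var_df: int = 2
    lag_df: int = 2
    trend_df_per_year: int = 2
    lag_percentile: float = 95.0
    lagspec_override: dict[str, int] | None = None
    # feature settings
    diff_mode: str = "full"
    # selection settings
    selection_trials: int = 40
    selection_alpha: float = 0.05
    selection_learner_params: dict[str, Any] = field(default_factory=dict)
    # learner settings
    leaves_grid: tuple[int, ...] = tuple(range(10, 101, 10))
    k_folds: int = 10
    fold_scheme: str = "random"
    learner_params: dict[str, Any] = field(default_factory=dict)
    # SMOGN / transfer settings
    use_smogn: bool = True
    rare_quantile: float = 0.90
    k_neighbors: int = 5
    noise_scale: float = 0.05
    target_multiplier: float = 1.3
    # projection settings
    scenario_offsets: dict[str, float] = field(
        default_factory=lambda: {"low": 1.0, "mid": 2.0, "high": 3.0}
    )
    percentile_levels: tuple[float, ...] = (50.0, 90.0, 95.0, 99.0)
    future_year_shift: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.diff_mode not in ("full", "first"):
            raise ValueError("diff_mode must be 'full' or 'first'")
        if self.fold_scheme not in ("random", "by_year"):
            raise ValueError("fold_scheme must be 'random' or 'by_year'")
        if not 1 <= self.max_lag:
            raise ValueError("max_lag must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0.0 < self.rare_quantile < 1.0:
            raise ValueError("rare_quantile must lie in (0, 1)")
        if self.target_multiplier < 1.0:
            raise ValueError("target_multiplier must be >= 1")
        if self.lagspec_override is not None:
            bad = {k: v for k, v in self.lagspec_override.items()
                   if not 1 <= int(v) <= self.max_lag}
            if bad:
                raise ValueError(f"lagspec_override entries out of [1, {self.max_lag}]: {bad}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["scenario"] = self.scenario.to_dict()
        d["leaves_grid"] = list(self.leaves_grid)
        d["percentile_levels"] = list(self.percentile_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "scenario" in d and isinstance(d["scenario"], dict):
            d["scenario"] = ScenarioConfig.from_dict(d["scenario"])
        if "leaves_grid" in d:
            d["leaves_grid"] = tuple(d["leaves_grid"])
        if "percentile_levels" in d:
            d["percentile_levels"] = tuple(d["percentile_levels"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
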