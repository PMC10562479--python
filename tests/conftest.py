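import numpy as np
import pandas as pd
import pytest

import heatlag as hl


@pytest.fixture(scope="session")
def scenario() -> hl.ScenarioConfig:
    return hl.ScenarioConfig()


@pytest.fixture(scope="session")
def target_weather(scenario) -> pd.DataFrame:
    return hl.generate_weather(scenario, "target")


@pytest.fixture(scope="session")
def target_mortality(scenario, target_weather):
    mortality, truth = hl.generate_mortality(target_weather, scenario)
    return mortality, truth


@pytest.fixture(scope="session")
def one_season_weather() -> pd.DataFrame:
    """A single 62-day season with a simple deterministic temperature curve."""
    dates = pd.date_range("2009-07-01", "2009-08-31", freq="D")
    rng = np.random.default_rng(42)
    tmax = 31.0 + 3.0 * np.sin(np.pi * np.arange(62) / 61) + rng.normal(0, 1.5, 62)
    frame = pd.DataFrame(
        {
            "date": dates,
            "tmax": tmax,
            "vap": 6.0 + 0.65 * tmax,
            "pres": 1009.0 + rng.normal(0, 2, 62),
            "rain": np.where(rng.random(62) < 0.3, rng.exponential(8, 62), 0.0),
        }
    )
    frame.attrs["city"] = "target"
    return frame
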