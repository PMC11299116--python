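import numpy as np
import pandas as pd
import pytest

from heatlag import met_features, synthetic


@pytest.fixture(scope="session")
def default_surface() -> synthetic.TrueLagSurface:
    """Geometric-decay lag surface over lags 0-5 above a 30 degC threshold."""
    return synthetic.TrueLagSurface.geometric(threshold=30.0, slope=0.05, max_lag=5)


@pytest.fixture(scope="session")
def five_season_dataset(default_surface) -> pd.DataFrame:
    cfg = synthetic.SyntheticConfig(
        seed=20140501, years=tuple(range(2014, 2019)), lag_effect=default_surface
    )
    return synthetic.generate_dataset(cfg)


@pytest.fixture(scope="session")
def six_season_features(default_surface) -> pd.DataFrame:
    """Six seasons with counts and the full derived-feature set joined on."""
    cfg = synthetic.SyntheticConfig(seed=7, lag_effect=default_surface)
    daily = synthetic.generate_dataset(cfg)
    calendar = synthetic.synthetic_sanfu_calendar(sorted(daily["year"].unique()))
    return met_features.add_met_features(daily, calendar=calendar)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
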