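import numpy as np
import pandas as pd
import pytest

from gxemet.synthetic import SimulationConfig, simulate_met


@pytest.fixture(scope="session")
def met_small():
    """Small but complete synthetic MET used by several modules' tests."""
    cfg = SimulationConfig(
        seed=7,
        n_inbreds=30,
        n_markers=200,
        n_hybrids=40,
        n_sites=3,
        n_years=3,
        hybrid_year_fraction=0.6,
    )
    return simulate_met(cfg)


@pytest.fixture()
def flat_daily():
    """A constant, benign daily weather series with derived columns."""

    def make(n_days=120, tmin=14.0, tmax=26.0, precip=0.0, start="2015-04-01"):
        idx = pd.date_range(start, periods=n_days, freq="D")
        df = pd.DataFrame(
            {
                "tmax": tmax,
                "tmin": tmin,
                "tmean": (tmax + tmin) / 2.0,
                "precip": precip,
                "rh": 60.0,
                "solar": 20.0,
                "wind": 2.0,
            },
            index=idx,
        )
        df.index.name = "date"
        for f in ("count", "range", "persistence", "consistency", "imputed"):
            df[f"flag_{f}"] = False
        return df

    return make
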