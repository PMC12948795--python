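import numpy as np
import pandas as pd
import pytest

from chronocog import actigraphy as act
from chronocog.chronotype import load_cmq_key
from chronocog.simulate import SimulationConfig


@pytest.fixture(scope="session")
def key():
    return load_cmq_key()


@pytest.fixture()
def small_config():
    """A fast study: 8 participants, 3 days, 6 sessions."""
    return SimulationConfig(
        n_participants=8,
        n_days=3,
        session_days=(0, 1, 2),
        rng_seed=123,
    )


def make_series(
    values,
    participant_id="P000",
    start="2024-01-01",
    epoch_seconds=60,
    missing_idx=(),
):
    """Build an EpochSeries from raw values with optional missing epochs."""
    vals = np.asarray(values, dtype=float).copy()
    if len(missing_idx):
        vals[np.asarray(missing_idx, dtype=int)] = np.nan
    idx = pd.date_range(start, periods=len(vals), freq=pd.Timedelta(seconds=epoch_seconds))
    return act.EpochSeries(participant_id, pd.Series(vals, index=idx), epoch_seconds)


@pytest.fixture()
def make_epoch_series():
    return make_series
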