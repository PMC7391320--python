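"""Shared fixtures: small synthetic datasets and hand-built survey tables."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from reefcascade.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        warnings.filterwarnings("ignore", message=".*separation.*")
        warnings.filterwarnings("ignore", message=".*Perfect separation.*")
        yield


def make_survey_frame(rows: list[dict]) -> pd.DataFrame:
    """Survey frame from sparse row dicts with sensible defaults."""
    defaults = {
        "region": "tropical",
        "location_id": "L1",
        "site_id": "s1",
        "transect_id": "t1",
        "year": 2000,
        "trophic_group": "predators",
        "value": 1.0,
        "value_kind": "density",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


def make_location_frame(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "location_id": "L1",
        "latitude": -20.0,
        "exploitation_status": "always_fished",
        "reserve_start_year": np.nan,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture(scope="session")
def small_dataset():
    """A 12-location default-scenario simulation (records, meta, truth)."""
    return simulate_dataset(SimulationConfig(n_locations=12, seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """The full 104-location default-scenario simulation."""
    return simulate_dataset(SimulationConfig(seed=23))
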