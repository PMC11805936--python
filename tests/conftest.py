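"""Shared fixtures: small synthetic scenarios and their derived products."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dioica.climate import ClimateTable
from dioica.synth import ScenarioConfig, generate_climate


@pytest.fixture(scope="session")
def default_scenario() -> ScenarioConfig:
    return ScenarioConfig(seed=7)


@pytest.fixture(scope="session")
def default_climate(default_scenario) -> ClimateTable:
    return generate_climate(default_scenario)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_scenario):
    """A full simulated fixture directory (session-scoped for speed)."""
    from dioica.pipeline import simulate

    out = tmp_path_factory.mktemp("fixtures")
    return simulate(default_scenario, out)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_climate_frame(
    years: range, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Minimal valid climate frame, optionally with random weather."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for y in years:
        for m in range(1, 13):
            t = 9.0 + 8.0 * np.cos(2 * np.pi * (m - 7) / 12) + rng.normal(0, 1)
            rows.append(
                {
                    "year": y,
                    "month": m,
                    "tmed": t,
                    "prec": float(rng.gamma(5.0, 16.0)),
                    "cld": float(np.clip(55 + rng.normal(0, 10), 0, 100)),
                    "pet": max(0.0, 40 + 30 * np.cos(2 * np.pi * (m - 7) / 12) + rng.normal(0, 5)),
                }
            )
    return pd.DataFrame(rows)
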