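"""Shared fixtures: synthetic scenarios rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from triposture.cli import analyze_traces
from triposture.synth import Rendered, SyntheticScenario, ground_truth, make_scenario, render


@pytest.fixture(scope="session")
def one_day_scenario() -> SyntheticScenario:
    """One full day under the default free-living conditions (noise + jitter)."""
    return make_scenario(seed=11, days=1)


@pytest.fixture(scope="session")
def one_day_rendered(one_day_scenario) -> Rendered:
    return render(one_day_scenario)


@pytest.fixture(scope="session")
def one_day_result(one_day_rendered):
    """Full pipeline output for the default one-day scenario."""
    r = one_day_rendered
    return analyze_traces(r.torso, r.thigh, r.shin, r.events, r.diary)


@pytest.fixture(scope="session")
def one_day_truth(one_day_scenario):
    return ground_truth(one_day_scenario)


@pytest.fixture(scope="session")
def lowrate_scenario() -> SyntheticScenario:
    """A 2 samples/s day for file-level round trips (small CSVs, same logic)."""
    return make_scenario(seed=5, days=1, sample_rate=2.0)


@pytest.fixture(scope="session")
def lowrate_rendered(lowrate_scenario) -> Rendered:
    return render(lowrate_scenario)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230104)
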