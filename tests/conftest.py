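"""Shared fixtures: cached simulation runs reused across test modules.

The heavyweight 60-h chemostat/Segregostat runs at desk scale (2,000 agents,
20,000-event measurements) are computed once per session and shared; a small
fast scenario is provided for plumbing tests.
"""

from __future__ import annotations

from dataclasses import replace
from functools import lru_cache

import numpy as np
import pytest

import segresim as sg

DESK_N = 2_000


@lru_cache(maxsize=None)
def preset_run(name: str, mode: str, seed: int) -> sg.SimulationResult:
    """One cached desk-scale run of a named preset.

    mode 'open' is the open-loop chemostat reference, 'closed' the
    Segregostat condition.
    """
    scenario = sg.load_preset(name, n_target=DESK_N)
    if mode == "open":
        scenario = scenario.open_loop()
    return sg.run_closed_loop(scenario, seed=seed)


@lru_cache(maxsize=None)
def preset_metrics(name: str, mode: str, seed: int) -> sg.MetricSeries:
    return sg.compute_metrics(preset_run(name, mode, seed))


@lru_cache(maxsize=None)
def washout_sweep():
    """Fitness-cost sweep 0.90..1.00 (1% steps) on the glc3 preset."""
    costs = [round(0.90 + 0.01 * i, 2) for i in range(11)]
    return sg.cost_sweep(sg.load_preset("glc3", n_target=DESK_N), costs, base_seed=1)


@pytest.fixture(scope="session")
def run_cached():
    return preset_run


@pytest.fixture(scope="session")
def metrics_cached():
    return preset_metrics


@pytest.fixture(scope="session")
def washout_table():
    return washout_sweep()


@pytest.fixture()
def quick_scenario():
    """A small, fast araB-like scenario for plumbing and determinism tests."""
    p = sg.load_preset("araB", n_target=300, duration_h=2.0, n_events=2_000)
    return p


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
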