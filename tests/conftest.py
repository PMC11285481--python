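"""Shared fixtures: array geometry, movement regimes, and one small
noise-free simulated pipeline reused by positioning/space-use tests."""

from __future__ import annotations

import numpy as np
import pytest

from reeftrack import positioning as pos_mod
from reeftrack import simulate as sim_mod


@pytest.fixture(scope="session")
def layout():
    return sim_mod.default_layout()


@pytest.fixture(scope="session")
def regimes():
    return sim_mod.default_regimes()


@pytest.fixture(scope="session")
def tag_config():
    return sim_mod.TagConfig()


TM3 = np.array(
    [
        [0.97, 0.028, 0.002],
        [0.015, 0.97, 0.015],
        [0.002, 0.048, 0.95],
    ]
)


@pytest.fixture(scope="session")
def small_pipeline(layout, regimes, tag_config):
    """2 fish x 1 day, noise-free timing, drifting clocks; full solve."""
    truth = sim_mod.simulate_tracks(layout, regimes, TM3, 2, 1.0, seed=7)
    clocks_true = sim_mod.random_clock_models(layout, seed=8)
    det, sync = sim_mod.simulate_detections(
        truth,
        layout,
        tag_config,
        clock_models=clocks_true,
        timing_sd=0.0,
        regimes=regimes,
        seed=9,
    )
    ref = str(layout.receivers["id"].iloc[0])
    clocks = pos_mod.synchronize_clocks(sync, layout, ref)
    positions, failures = pos_mod.positions_from_detections(det, layout, clocks)
    return {
        "truth": truth,
        "detections": det,
        "sync": sync,
        "clocks_true": clocks_true,
        "clocks": clocks,
        "positions": positions,
        "failures": failures,
        "reference": ref,
    }
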