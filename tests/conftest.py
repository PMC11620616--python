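"""Shared fixtures.

The ``study`` fixture builds the whole desk-scale experiment once per
session: three simulated training recordings, a detector trained on
semi-synthetic samples from them, a separate simulated test recording with
six units at 0.5–2 Hz, the offline sorting result and the streaming replay.
Everything is seeded; the fixture takes a few minutes and is shared by the
end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from propsort import (
    UnitConfig,
    make_probe,
    make_unit,
    mea_params,
    replay_chunks,
    run_offline,
    run_streaming,
    simulate,
)
from propsort.detector.train import Hyperparams
from propsort.pipeline import build_sources, train_from_sources, units_from_ground_truth
from propsort.recording import amplitude_deviation

RATE = 20000.0
# six roots pairwise ≥70 μm apart on the 5×5 grid: "well separated" means
# no two units share inner electrodes at their roots
ROOTS = [0, 2, 4, 10, 14, 22]


def make_test_units(rng, geom, n, rates, amps, rate=RATE):
    """Six propagating units with roots spread over the array, paths aimed
    inward so the 100 μm propagation stays on the probe."""
    centroid = geom.positions.mean(axis=0)
    units = []
    for i in range(n):
        d = centroid - geom.positions[ROOTS[i]]
        ang = float(np.degrees(np.arctan2(d[1], d[0])) + rng.uniform(-35, 35))
        cfg = UnitConfig(
            root_electrode=ROOTS[i],
            direction_deg=ang,
            path_length_um=100.0,
            root_amplitude=float(amps[i]),
            decay_um=45.0,
            rate_hz=float(rates[i]),
        )
        units.append(make_unit(rng, geom, cfg, rate, unit_id=i))
    return units


@dataclass
class Study:
    geom: object
    params: object
    sources: list
    detector: object
    training_dev: float
    recording: object
    ground_truth: object
    offline: object
    stream_events: list


@pytest.fixture(scope="session")
def grid():
    return make_probe("grid35", 5, 5)


@pytest.fixture(scope="session")
def study(grid):
    params = mea_params()
    raw = []
    for si, seed in enumerate((101, 202, 303)):
        rng = np.random.default_rng(seed)
        units = make_test_units(
            rng, grid, 6, rng.uniform(1.0, 2.0, 6), rng.uniform(25, 45, 6)
        )
        rec, gt = simulate(units, 45.0, 3.0, rng, grid, RATE)
        raw.append((f"sim{si}", rec, units_from_ground_truth(gt)))
    sources, training_dev = build_sources(raw, params)
    detector, _ = train_from_sources(
        sources,
        RATE,
        n_filters=16,
        seed=7,
        hyper=Hyperparams(max_epochs=12, shuffle_seed=7),
        samples_per_waveform_train=12,
        samples_per_waveform_val=2,
    )
    rng = np.random.default_rng(999)
    units = make_test_units(
        rng, grid, 6, rng.uniform(0.5, 2.0, 6), rng.uniform(25, 45, 6)
    )
    recording, gt = simulate(units, 60.0, 3.0, rng, grid, RATE)
    offline = run_offline(recording, detector, training_dev, params, seed=3)
    scale = training_dev / amplitude_deviation(recording)
    events = list(
        run_streaming(
            replay_chunks(recording, 2000),
            detector,
            offline.sequences,
            params,
            grid,
            scale,
        )
    )
    return Study(
        geom=grid,
        params=params,
        sources=sources,
        detector=detector,
        training_dev=training_dev,
        recording=recording,
        ground_truth=gt,
        offline=offline,
        stream_events=events,
    )
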