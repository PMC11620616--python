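"""Glue from simulated ground truth to a trained detector.

The detector-training pipeline mirrors what one would do with real sorted
recordings, but takes its "sorted units" from the simulator's ground truth:
curate units, average waveform footprints into a bank, harvest spike-free
noise snippets, synthesize semi-synthetic samples and train.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .detector.net import SpikeDetector, build_detector
from .detector.train import Hyperparams, train_detector
from .params import Params, mea_params
from .recording import Recording, amplitude_deviation, read_recording
from .simulate import GroundTruth
from .training_data import (
    DetectorSource,
    SortedUnit,
    build_epoch,
    build_waveform_bank,
    curate_units,
    extract_noise_snippets,
)

__all__ = [
    "units_from_ground_truth",
    "build_sources",
    "train_from_sources",
    "train_from_recordings",
]


def units_from_ground_truth(gt: GroundTruth) -> list[SortedUnit]:
    """Ground-truth units as sorted units (main electrode = root)."""
    return [
        SortedUnit(
            unit_id=u.unit_id,
            spike_frames=np.sort(gt.spike_frames[u.unit_id]),
            main_electrode=u.root_electrode,
        )
        for u in gt.units
    ]


def build_sources(
    recordings: list[tuple[str, Recording, list[SortedUnit]]],
    params: Params | None = None,
) -> tuple[list[DetectorSource], float]:
    """Curate, bank and noise-harvest each recording.

    The *training amplitude deviation* is the mean amplitude deviation over
    the recordings; banks and noise pools are stored in the scaled units
    the detector will see at inference.
    """
    params = params or mea_params()
    devs = [amplitude_deviation(rec) for _, rec, _ in recordings]
    train_dev = float(np.mean(devs))
    sources = []
    for (name, rec, units), dev in zip(recordings, devs):
        scale = train_dev / dev
        round1, round2 = curate_units(units, rec)
        bank = build_waveform_bank(rec, round2, params, scale=scale)
        troughs = (
            np.sort(np.concatenate([u.spike_frames for u in round1]))
            if round1
            else np.empty(0, np.int64)
        )
        noise = extract_noise_snippets(rec, troughs, scale=scale)
        sources.append(DetectorSource(name=name, bank=bank, noise_snippets=noise))
    return sources, train_dev


def train_from_sources(
    sources: list[DetectorSource],
    sampling_rate: float,
    n_filters: int = 16,
    seed: int = 0,
    val_index: int | None = None,
    hyper: Hyperparams | None = None,
    samples_per_waveform_train: int = 20,
    samples_per_waveform_val: int = 2,
):
    """Build one epoch corpus and train a fresh detector on it.

    Returns ``(detector, history)``.  The corpus is synthesized once with
    the given seed and iterated in a new shuffled order every epoch.
    """
    if val_index is None:
        val_index = len(sources) - 1
    rng = np.random.default_rng(seed)
    train_set, val_set = build_epoch(
        sources,
        val_index,
        sampling_rate,
        samples_per_waveform_train,
        samples_per_waveform_val,
        rng,
    )
    det = build_detector(sampling_rate, n_filters=n_filters, seed=seed)
    hyper = hyper or Hyperparams(shuffle_seed=seed)
    det, history = train_detector(det, train_set, val_set, hyper)
    return det, history


def _load_ground_truth_units(path: Path) -> list[SortedUnit]:
    units: dict[int, list[int]] = {}
    for line in (path / "ground_truth.csv").read_text().splitlines()[1:]:
        u, f = line.split(",")
        units.setdefault(int(u), []).append(int(f))
    meta = json.loads((path / "meta.json").read_text())
    del meta
    out = []
    for uid, frames in sorted(units.items()):
        out.append(
            SortedUnit(
                unit_id=uid,
                spike_frames=np.asarray(sorted(frames), dtype=np.int64),
                main_electrode=0,  # refined below from the traces
            )
        )
    return out


def _load_sources_from_paths(paths: list[Path], params: Params | None = None):
    recs = []
    for p in paths:
        rec = read_recording(p)
        units = _load_ground_truth_units(p)
        for u in units:
            # main electrode: deepest average trough across spikes
            half = rec.ms_to_frames(0.5)
            frames = u.spike_frames[
                (u.spike_frames > half) & (u.spike_frames < rec.n_frames - half)
            ]
            segs = np.stack(
                [rec.traces[f - half : f + half + 1] for f in frames[:200]]
            ).mean(axis=0)
            u.main_electrode = int(segs.min(axis=0).argmin())
        recs.append((str(p), rec, units))
    return build_sources(recs, params)


def train_from_recordings(
    paths: list[Path], sampling_rate: float, n_filters: int, seed: int
):
    """CLI entry: train on simulated recording directories."""
    sources, train_dev = _load_sources_from_paths(paths)
    det, history = train_from_sources(
        sources, sampling_rate, n_filters=n_filters, seed=seed
    )
    return det, train_dev, history
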