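# propsort

Real-time spike detection and sorting for high-density extracellular
recordings, based on **axonal action-potential propagation sequences**
rather than waveform templates.

On dense arrays (≤50 μm pitch — MEAs at 35 μm, Neuropixels checkerboard
configurations) a single neuron's action potential crosses several
electrodes in a fixed order with sub-millisecond latencies.  `propsort`
identifies neurons by that recurring spatiotemporal detection order, which
makes it robust to overlapping waveforms and lets it assign spikes on a
live stream with millisecond-scale algorithmic latency.  It is aimed at
electrophysiologists working with MEA or silicon-probe recordings who need
sorted units online (closed-loop experiments) or a template-free offline
sorter, and at methods developers who want every stage — detector,
training-data synthesis, sequence detection, merging, evaluation,
ground-truth simulation — as a testable library.

## The method in brief

**Detection.**  A small convolutional network (four conv layers, kernel =
frames in 1 ms + 1, stride 1) maps each electrode's raw, unfiltered 10 ms
window onto per-frame trough likelihoods *s(t) ∈ [0, 100]* for the frames
2–8 ms inside the window, each frame seeing ±2 ms of context.  It trains on
semi-synthetic data: averaged real waveforms pasted into spike-free device
noise at known trough frames (0–4 waveforms per sample with probabilities
50/30/12/6/2 %, pairwise trough spacings in [0.2, 6] ms).  Two score
thresholds gate detections: *stringent* (F1-optimal; root detections) and
*loose* (recall-first; supporting detections).

**Amplitudes.**  Every amplitude is standardized against the preceding
50 ms window: *a = (x − A) / max(0.5, B)* with *A* = median(window) and
*B* = median(|window − A|)/0.6745, a robust noise SD.

**Sorting.**  Root detections (stringent, locally amplitude-dominant
within 100 μm, co-detected within 0.1 ms on an inner electrode) are
compared with co-detections on neighboring electrodes; 1–4-component
Gaussian mixtures selected by BIC split the interelectrode-interval
distributions where multiple neurons share electrodes, and Hartigan's dip
test (P < 0.1) gates an amplitude-based split.  Each resulting
*propagation sequence* carries per-electrode median detection scores, mean
interelectrode intervals and mean amplitudes.  A spike joins a sequence
only when enough loose electrodes co-detect it and its score-weighted
interval and amplitude differences stay below device-specific thresholds
(3.5 frames / 65 % for MEAs; 2.5 frames / 45 % for Neuropixels); duplicate
claims within 0.2 ms are resolved by a difference score, and over-split
sequences merge in two greedy rounds.  Online mode freezes sequence
metrics from a pre-recording and scores a 10 ms window every 5 ms.

A ground-truth simulator (propagating units with fixed per-electrode
latencies, Poisson firing, Gaussian noise) generates the recordings used
throughout the test suite.  See `docs/methods.md` for the full model,
parameter tables, numerical choices and limitations.

## Worked example

Simulate training recordings, train a compact detector on semi-synthetic
samples, sort a fresh 60 s recording offline and compare against ground
truth:

```python
import numpy as np
from propsort import (
    UnitConfig, make_probe, make_unit, mea_params, simulate,
    run_offline, overlap_score, precision_recall,
)
from propsort.pipeline import build_sources, train_from_sources, units_from_ground_truth
from propsort.detector.train import Hyperparams

RATE, N = 20000.0, 6
grid = make_probe("grid35", 5, 5)
roots = [0, 2, 4, 10, 14, 22]          # pairwise ≥70 μm apart

def make_units(rng, rates, amps):
    centroid = grid.positions.mean(axis=0)
    units = []
    for i in range(N):
        d = centroid - grid.positions[roots[i]]
        ang = float(np.degrees(np.arctan2(d[1], d[0])) + rng.uniform(-35, 35))
        cfg = UnitConfig(root_electrode=roots[i], direction_deg=ang,
                         root_amplitude=float(amps[i]), decay_um=45.0,
                         rate_hz=float(rates[i]))
        units.append(make_unit(rng, grid, cfg, RATE, unit_id=i))
    return units

raw = []
for si, seed in enumerate((101, 202, 303)):
    rng = np.random.default_rng(seed)
    units = make_units(rng, rng.uniform(1, 2, N), rng.uniform(25, 45, N))
    rec, gt = simulate(units, 45.0, 3.0, rng, grid, RATE)
    raw.append((f"sim{si}", rec, units_from_ground_truth(gt)))
sources, training_dev = build_sources(raw, mea_params())

detector, history = train_from_sources(
    sources, RATE, n_filters=16, seed=7,
    hyper=Hyperparams(max_epochs=12, shuffle_seed=7),
    samples_per_waveform_train=12,
)
print(f"trained: best val loss {history.val_loss.min():.4f}")

rng = np.random.default_rng(999)
units = make_units(rng, rng.uniform(0.5, 2, N), rng.uniform(25, 45, N))
recording, gt = simulate(units, 60.0, 3.0, rng, grid, RATE)

result = run_offline(recording, detector, training_dev, mea_params(), seed=3)
print(f"{len(result.sequences)} propagation sequences detected")
for sid, train in sorted(result.spike_trains.items()):
    best = max(gt.units,
               key=lambda u: overlap_score(gt.spike_frames[u.unit_id], train, RATE).overlap)
    ov = overlap_score(gt.spike_frames[best.unit_id], train, RATE).overlap
    p, r = precision_recall(gt.spike_frames[best.unit_id], train, RATE)
    print(f"  sequence {sid}: {len(train):3d} spikes -> unit {best.unit_id} "
          f"(overlap {ov:.2f}, precision {p:.2f}, recall {r:.2f})")
```

Output (a few minutes on one CPU):

```
trained: best val loss 0.0119
6 propagation sequences detected
  sequence 0:  98 spikes -> unit 2 (overlap 0.97, precision 1.00, recall 0.97)
  sequence 1:  67 spikes -> unit 0 (overlap 0.67, precision 1.00, recall 0.67)
  sequence 2: 105 spikes -> unit 3 (overlap 0.96, precision 1.00, recall 0.96)
  sequence 3:  52 spikes -> unit 4 (overlap 0.98, precision 1.00, recall 0.98)
  sequence 4:  97 spikes -> unit 5 (overlap 0.99, precision 1.00, recall 0.99)
  sequence 5:  38 spikes -> unit 1 (overlap 1.00, precision 1.00, recall 1.00)
```

Every sequence maps to a distinct true unit with precision 1.00: spikes
the sorter emits belong to the right neuron.  The overlap score
(#matches / (#A + #B − #matches), 0.4 ms tolerance) is bounded here by
recall; the weakest unit (0) sits in the array corner where only three
electrodes lie within 50 μm of its root, the hardest geometry for a
propagation-based sorter.  For online use, `run_streaming` replays or ingests chunked data
against the frozen sequences and emits `SortedEvent`s with a per-event
latency breakdown.

A `propsort` command-line tool wraps the common steps
(`propsort simulate`, `make-training-data`, `train-detector`, `detect`,
`find-sequences`, `sort-offline`, `sort-stream`, `evaluate`); every run writes a provenance record with its profile and
seeds.

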