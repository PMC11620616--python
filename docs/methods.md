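# Methods

## The problem and the approach

Dense extracellular arrays (MEAs at 35 μm pitch, Neuropixels checkerboard
configurations) record each neuron on several electrodes at once.  As an
action potential travels along the axon it crosses those electrodes in a
fixed order with sub-millisecond latencies.  `propsort` identifies neurons
by that *propagation sequence* — the recurring spatiotemporal order of
detections — rather than by waveform template matching, and assigns spikes
to sequences either offline or on a live stream.

The pipeline has two halves:

1. a per-electrode convolutional **trough detector** that turns raw,
   unfiltered traces into per-frame spike-trough likelihood scores in
   [0, 100], and
2. a **sequence sorter** that clusters co-detections across neighboring
   electrodes into per-neuron sequences and then assigns individual spikes
   to them by interelectrode-interval and amplitude agreement.

## Detector

**Architecture.**  Four 1-D convolutional layers, stride 1, kernel equal to
the frames in 1 ms of data plus one (21 at 20 kHz, 31 at 30 kHz).  The
first three layers have rectifier nonlinearities; the hidden width defaults
to 50 filters (`DetectorConfig.n_filters`).  The output layer is a single
filter with a sigmoid scaled to [0, 100].  A 10 ms input window therefore
maps onto the frames between 2 and 8 ms of the window (120 outputs at
20 kHz, 180 at 30 kHz), each output frame seeing exactly ±2 ms of raw
context.  Windows are median-subtracted (removing slow LFP offsets) and
processed in float32; convolutions are lowered to a direct numba kernel.

**Semi-synthetic training data.**  Ground truth at scale comes from pasting
*averaged* spike waveforms into spike-free device noise.  Units are curated
in two rounds (≥30 spikes, <1 % inter-spike-interval violations at 1.5 ms,
SNR > 5; then ≥50 spikes for averaging); electrodes enter the waveform bank
when the averaged trough crosses −19 μV (MEA profile; −36 μV Neuropixels) or
a positive peak at twice the trough crosses the same cutoff, with a
peak-stability ratio std/|mean| ≤ 0.6.  Noise snippets are 10 ms windows
with no curated trough within 3 ms of either end.  Each synthesized sample
pastes 0–4 distinct bank waveforms with probabilities 50/30/12/6/2 %,
troughs uniform in the scored 2–8 ms span, rejection-sampled until all
pairwise spacings lie in [0.2 ms, 6 ms] (100 failed draws reduce the count
by one).  Epochs follow a cross-validation fold structure: the held-out
source recording contributes neither waveforms nor noise to training.

**Training.**  SGD, batch size 1, momentum 0.85, initial learning rate
7.76·10⁻⁴ (2·10⁻⁴ Neuropixels profile).  The loss — not fixed by the
design being reimplemented — is per-output-frame binary cross-entropy with
target 1 exactly at ground-truth trough frames; this matches the
single-frame detection peaks the detector is expected to produce.  The
learning rate drops ×0.4 after more than five epochs without the minimum
validation improvement, training stops after ten stalled epochs, and the
best-validation-epoch weights are kept.

**Thresholds.**  Two score cutoffs are calibrated on validation samples:
*stringent* at the F1 optimum (ties resolved to the highest threshold,
favouring precision) and *loose* where recall exceeds precision by about 15
points.  The shipped profile defaults are 27.5/10 % (MEA) and 17.5/7.5 %
(Neuropixels).  Detection events are local score maxima above threshold
with ±0.5 ms non-maximum suppression (earliest frame wins a plateau).

**Inference scaling.**  Traces are multiplied by (training amplitude
deviation)/(recording amplitude deviation), where the amplitude deviation
is the median over electrodes of the IQR of the first 50 ms.  Offline,
10 ms windows are tiled with a 6 ms stride (plus one tail window) so every
interior frame is scored exactly once; streaming advances windows by 5 ms
and a frame is owned by the earliest window whose scored interior contains
it.

## Sequence detection

All amplitudes are *standardized*: (value − median of the preceding 50 ms) /
max(0.5, MAD/0.6745).  Root detections are stringent detections that are
local amplitude maxima (no larger standardized amplitude within ±0.5 ms on
any electrode within 100 μm) with at least one stringent co-detection
within ±0.1 ms on an electrode within 50 μm; electrodes below 0.05 Hz are
dropped and frames with array-wide simultaneous stringent detections
(max(100, 10 %) electrodes) are discarded as noise.

Per root electrode, co-detection intervals on each nearby "splitting"
electrode (visited in ascending distance, ties by id) are clustered with
1–4-component Gaussian mixtures selected by BIC; negative-BIC models and
numerically failed fits are ignored (all ignored → single component).
Clusters below max(10, 10 % of the co-detections) are discarded; their
members return to the root pool and may seed clusters on later electrodes.
Growth is breadth-recursive: surviving clusters shrink to their
co-detecting members at each subsequent electrode, branch when the mixture
separates them, expand the electrode list with the splitting electrode's
own neighbors when ≥50 % of the detections travel together, and stop after
six consecutive equal-distance tiers without a membership change.

Two numerical choices in the splitting are this package's own.  First,
intervals are integer frames, and BIC on lattice-valued data rewards
components that collapse onto single frame levels; seeded U(−0.5, 0.5)
dequantization jitter is added to the interval sample before fitting (the
negative-BIC guard still removes the fully collapsed fits).  Second,
mixture components whose means are within 2 frames are treated as one
mode: the downstream assignment thresholds are 2.5–3.5 frames, so closer
modes are not separable by the method in any case.

A preliminary sequence whose root-amplitude distribution is not unimodal
(Hartigan's dip test, P < 0.1) is split by a BIC-selected 2–4 component
mixture; post-split sequences with fewer than 10 spikes are dropped.  The
dip statistic is computed exactly (bisection over the sup-norm distance to
the nearest unimodal CDF, using convex-hull band feasibility); p-values are
calibrated by parametric bootstrap against the uniform null — the least
favourable unimodal distribution — with 2000 replicates and a fixed seed,
cached per sample size.  Two closed forms pin the implementation down:
equally spaced samples have dip 1/(2n) and a half-and-half two-point sample
has dip 1/4.  On heavily quantized amplitude samples the dip is inflated by
the discreteness itself; real device amplitudes avoid this because the
robust noise scale varies from window to window.

**Metrics.**  For each member spike and each electrode near the sequence,
the score maximum within ±0.5 ms of the root detection gives the
electrode's detection score, its frame offset from the root's maximum gives
the interelectrode interval, and the standardized amplitude at that frame
gives the amplitude.  Per-electrode medians/means over members define:
loose electrodes (median score above the loose threshold, within 50 μm of a
splitting electrode), inner-loose (loose within 50 μm of the root), and the
footprint (loose plus everything within 50 μm of a loose electrode).
Median scores below 3 % are zeroed.  Sequences with <4 loose or <3
inner-loose electrodes, or with more than max(50, 5 %) loose electrodes
(array-wide noise), are discarded.

## Assignment, duplicates, merging

A spike (stringent root detection) joins a sequence only if: its root
amplitude is within 2.5 SD of the sequence's root-amplitude distribution;
≥3 inner-loose and max(4, ⌈33 %⌉ of loose) electrodes detect above the
loose threshold in the propagation period; and the score-weighted
interelectrode-interval and amplitude percent differences (clipped at twice
the thresholds) stay within 3.5 frames / 65 % (MEA) or 2.5 frames / 45 %
(Neuropixels).  When several sequences claim events within 0.2 ms on the
same or mutually-inner root electrodes, the lowest difference score
(interval term + amplitude term − 0.5 × fraction of loose electrodes
detecting) wins; ties break to the lower sequence id for determinism.

Merging runs in two greedy rounds — same root electrode, then mutually
inner roots — lowest merge score first, pooling member spikes and
re-extracting metrics after every merge.  The root electrode is excluded
from the merge interval term; amplitude differences use the midpoint
method; the root-amplitude z ≤ 2.5 condition applies to the Neuropixels
profile by default (configurable).  Between rounds each root may relocate
to a loose electrode with ≥80 % of the root amplitude, a stringent median
score and a mean interval below −2 frames; after round two the root moves
to the highest-median-score electrode and intervals are re-referenced.

Offline sorting = score → detect sequences → reassign (same-root
deduplication) → merge → final reassignment with full deduplication.
Online sorting freezes the sequence metrics from a pre-recording and runs
the same assignment per 5 ms tick with a short look-back buffer, so events
near window seams are decided at the next tick rather than dropped; the
emitted stream is a function of stream content only (re-chunking the same
recording yields identical events).  Per-event latency is decomposed into
biological wait (trough-to-decidability, including the windowing delay),
detection compute and sorting compute; wall-clock values are reported but
never asserted against — they are hardware-bound.

## Simulator (ground truth)

The simulator emulates the statistical structure the sorter assumes, not
membrane biophysics: each unit is a biphasic trough-dominant template
deposited on a set of electrodes with fixed per-electrode latencies
(linear in the projection onto a straight propagation path, total ≤0.5 ms)
and amplitudes decaying exponentially with distance from the root
(space constant 40–45 μm by default).  Units fire as independent Poisson
processes with a 2 ms refractory floor (configurable to 0), per-spike
latency jitter (SD 0.5 frames) and amplitude jitter (SD 8 %); white
Gaussian noise is added on top and traces are quantized to int16.  The
exact spike times and realized per-spike latencies/amplitudes are retained,
and the float clean/noise parts can be returned so additivity is auditable
exactly.

What this does *not* emulate: electrode drift, correlated (colored) device
noise, bursting and rate nonstationarity, electrical stimulation artifacts,
and waveform shape diversity beyond amplitude scaling of one template
family.  Tests passing on this simulator therefore demonstrate the
pipeline's correctness under its own model assumptions, not performance on
real tissue.

## Desk-scale study conditions

The end-to-end suite and fixtures use sizes chosen to exercise every stage
on a single CPU:

* probe: 35 μm square grid, 5×5 (25 electrodes);
* six units with roots pairwise ≥70 μm apart (well separated — no shared
  inner electrodes), 100 μm propagation paths aimed into the array,
  root amplitudes 25–45 ADC, noise SD 3 ADC (root SNR ≈ 6–13);
* three 45 s training recordings (rates 1–2 Hz) feed curation, waveform
  banks and noise pools; the detector trains with 16 hidden filters for 12
  epochs on 12 samples per bank waveform;
* the test recording is 60 s with rates 0.5–2 Hz; offline sorting and a
  full streaming replay run on it.

Two neurons sharing a root electrode, amplitude-bimodal contamination, and
the other splitting scenarios are exercised by dedicated constructed cases
rather than the recovery fixture.  Units whose roots sit within each
other's inner radius with near-parallel axons can legitimately merge in
round two — the method's resolution limit — which is why the recovery
claim is stated for well-separated units.

## Known limitations

* The recursive growth keeps only members stringently co-detected on each
  successive splitting electrode, so low-SNR units fragment into several
  preliminary sequences; same-root merging re-fuses them, but recall for
  units with few detecting electrodes (e.g., corner roots with three inner
  neighbors) remains lower.
* Dip-test p-values are bootstrap-calibrated against the uniform null;
  on strongly discrete amplitude samples the test over-rejects
  unimodality.
* No drift correction: sequences are assumed stationary between the
  pre-recording and the live stream.
* Streaming scores differ from offline scores by the per-window median
  (window alignments differ), so offline/online spike assignments agree to
  ≥99 %, not bit-exactly.
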