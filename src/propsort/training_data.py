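"""Semi-synthetic detector training data.

Ground truth at scale is scarce in extracellular electrophysiology, so the
detector trains on *semi-synthetic* samples: real (or simulated) device
noise snippets with averaged spike waveforms pasted in at known trough
frames.  This module implements the full pipeline:

* two-round curation of sorted units (spike count, refractory violations,
  SNR on the main electrode),
* per-electrode waveform selection from averaged unit footprints
  (trough/peak amplitude cutoffs and a peak-stability ratio),
* extraction of spike-free 10 ms noise snippets (3 ms guard band), and
* sample synthesis: 0–4 waveforms per snippet with probabilities
  50/30/12/6/2 % and pairwise trough spacings confined to 0.2–6 ms.

Epochs are assembled with a cross-validation fold structure: a held-out
source recording contributes neither waveforms nor noise to training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import Params
from .recording import Recording, amplitude_deviation

__all__ = [
    "SortedUnit",
    "WaveformBankEntry",
    "WaveformBank",
    "TrainingSample",
    "DetectorSource",
    "PASTE_COUNT_PROBS",
    "curate_units",
    "electrode_passes_selection",
    "build_waveform_bank",
    "extract_noise_snippets",
    "synthesize_sample",
    "build_epoch",
]

# probability of pasting 0..4 waveforms into one sample
PASTE_COUNT_PROBS = np.array([0.50, 0.30, 0.12, 0.06, 0.02])
MIN_SPACING_MS = 0.2
MAX_SPACING_MS = 6.0
NOISE_GUARD_MS = 3.0
ISI_VIOLATION_MS = 1.5
MAX_ISI_VIOLATION_FRACTION = 0.01
MIN_SPIKES_ROUND1 = 30
MIN_SPIKES_ROUND2 = 50
MIN_SNR = 5.0
PEAK_TO_TROUGH_FACTOR = 2.0
MAD_TO_SD = 0.6745


@dataclass
class SortedUnit:
    """A sorted unit: spike trough frames and its main (peak) electrode."""

    unit_id: int
    spike_frames: np.ndarray
    main_electrode: int


@dataclass
class WaveformBankEntry:
    source_unit: int
    source_electrode: int
    waveform: np.ndarray  # averaged, trough-centred, scaled units
    trough_index: int
    trough_amplitude: float
    peak_amplitude: float
    stability: float  # std(per-spike amplitude) / |mean amplitude|


@dataclass
class WaveformBank:
    entries: list[WaveformBankEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class TrainingSample:
    """A 10 ms trace with zero or more pasted waveforms.

    ``gt_troughs`` are trough frames within the window (each inside the
    scored 2–8 ms span); ``sources`` index the bank entries pasted.
    """

    trace: np.ndarray
    gt_troughs: list[int]
    sources: list[int]


# --------------------------------------------------------------------- units
def _isi_violation_fraction(frames: np.ndarray, sampling_rate: float) -> float:
    if frames.size < 2:
        return 0.0
    limit = ISI_VIOLATION_MS * sampling_rate / 1000.0
    return float(np.mean(np.diff(np.sort(frames)) < limit))


def unit_snr(unit: SortedUnit, recording: Recording, window_ms: float = 1.0) -> float:
    """Trough depth of the averaged main-electrode waveform over the robust
    noise scale (MAD/0.6745) of that electrode's trace."""
    trace = recording.traces[:, unit.main_electrode].astype(np.float64)
    half = recording.ms_to_frames(window_ms)
    segs = []
    for f in unit.spike_frames:
        f = int(f)
        if f - half >= 0 and f + half < trace.size:
            segs.append(trace[f - half : f + half + 1])
    if not segs:
        return 0.0
    avg = np.mean(segs, axis=0)
    baseline = np.median(trace)
    depth = float(baseline - avg.min())
    mad = np.median(np.abs(trace - baseline))
    noise = max(mad / MAD_TO_SD, 1e-9)
    return depth / noise


def curate_units(
    units: list[SortedUnit], recording: Recording
) -> tuple[list[SortedUnit], list[SortedUnit]]:
    """Two curation rounds.

    Round 1 (≥30 spikes, <1 % ISI violations at 1.5 ms, SNR > 5) defines
    the set whose spikes count as "all spikes in the recording" (used for
    noise-snippet exclusion).  Round 2 (the round-1 units with ≥50 spikes)
    feeds waveform averaging.
    """
    round1 = []
    for u in units:
        if u.spike_frames.size < MIN_SPIKES_ROUND1:
            continue
        if _isi_violation_fraction(u.spike_frames, recording.sampling_rate) >= (
            MAX_ISI_VIOLATION_FRACTION
        ):
            continue
        if unit_snr(u, recording) <= MIN_SNR:
            continue
        round1.append(u)
    round2 = [u for u in round1 if u.spike_frames.size >= MIN_SPIKES_ROUND2]
    return round1, round2


# ----------------------------------------------------------------- waveforms
def electrode_passes_selection(
    avg_waveform: np.ndarray,
    per_spike_amplitudes: np.ndarray,
    params: Params,
) -> bool:
    """Whether one electrode of a unit footprint enters the waveform bank.

    The electrode is selected if its averaged trough crosses the device
    cutoff (−19 μV MEA / −36 μV Neuropixels), or if it shows a positive
    peak at least twice the trough that itself crosses the cutoff; in
    addition the per-spike amplitude must be stable:
    std(amplitudes)/|mean| ≤ 0.6.
    """
    w = np.asarray(avg_waveform, dtype=np.float64)
    trough = float(w.min())
    peak = float(w.max())
    cut = params.waveform_trough_uv
    amp_ok = trough <= -cut or (
        peak >= PEAK_TO_TROUGH_FACTOR * abs(trough) and peak >= cut
    )
    if not amp_ok:
        return False
    amps = np.asarray(per_spike_amplitudes, dtype=np.float64)
    mean = np.mean(amps)
    if mean == 0:
        return False
    return float(np.std(amps) / abs(mean)) <= params.waveform_stability_max


def build_waveform_bank(
    recording: Recording,
    units: list[SortedUnit],
    params: Params,
    waveform_ms: float = 5.0,
    scale: float = 1.0,
) -> WaveformBank:
    """Average each unit's footprint and keep the electrodes that pass
    selection.  ``scale`` converts to the amplitude range the detector sees
    at inference (training amplitude deviation / recording deviation)."""
    half = recording.ms_to_frames(waveform_ms / 2.0)
    bank = WaveformBank()
    for u in units:
        frames = [
            int(f)
            for f in u.spike_frames
            if f - half >= 0 and f + half < recording.n_frames
        ]
        if not frames:
            continue
        segs = np.stack(
            [recording.traces[f - half : f + half + 1].astype(np.float64) for f in frames]
        )  # (spikes, frames, electrodes)
        segs -= np.median(segs, axis=1, keepdims=True)
        avg = segs.mean(axis=0)
        for e in range(recording.n_electrodes):
            w = avg[:, e]
            trough_rel = int(np.argmin(w))
            per_spike = segs[:, trough_rel, e]
            if not electrode_passes_selection(w, per_spike, params):
                continue
            centred = np.roll(w, half - trough_rel)
            bank.entries.append(
                WaveformBankEntry(
                    source_unit=u.unit_id,
                    source_electrode=e,
                    waveform=(centred * scale).astype(np.float32),
                    trough_index=half,
                    trough_amplitude=float(w.min() * scale),
                    peak_amplitude=float(w.max() * scale),
                    stability=float(
                        np.std(per_spike) / max(abs(np.mean(per_spike)), 1e-12)
                    ),
                )
            )
    return bank


# -------------------------------------------------------------------- noise
def extract_noise_snippets(
    recording: Recording,
    all_spike_troughs: np.ndarray,
    window_ms: float = 10.0,
    scale: float = 1.0,
) -> np.ndarray:
    """Spike-free 10 ms snippets, per electrode.

    A window is eligible when no curated spike trough falls within 3 ms of
    either end.  Returns an array (n_electrodes, n_windows, window_frames)
    in the scaled units the detector sees.
    """
    win = recording.ms_to_frames(window_ms)
    guard = recording.ms_to_frames(NOISE_GUARD_MS)
    troughs = np.sort(np.asarray(all_spike_troughs, dtype=np.int64))
    starts = []
    for s in range(0, recording.n_frames - win + 1, win):
        lo, hi = s - guard, s + win + guard
        i = np.searchsorted(troughs, lo, side="left")
        if i < troughs.size and troughs[i] < hi:
            continue
        starts.append(s)
    if not starts:
        return np.empty((recording.n_electrodes, 0, win), dtype=np.float32)
    snips = np.stack(
        [recording.traces[s : s + win].astype(np.float32) * scale for s in starts]
    )  # (n_windows, win, n_elec)
    return np.ascontiguousarray(snips.transpose(2, 0, 1))


# ----------------------------------------------------------------- synthesis
def _draw_troughs(
    rng: np.random.Generator, count: int, margin: int, span: int, fpms: float
) -> list[int] | None:
    min_gap = int(round(MIN_SPACING_MS * fpms))
    max_gap = int(round(MAX_SPACING_MS * fpms))
    for _ in range(100):
        t = np.sort(rng.integers(margin, margin + span, size=count))
        d = np.diff(t)
        if count >= 2 and (np.any(d < min_gap) or (t[-1] - t[0]) > max_gap):
            continue
        return [int(x) for x in t]
    return None


def synthesize_sample(
    noise_snippet: np.ndarray,
    bank: WaveformBank,
    rng: np.random.Generator,
    sampling_rate: float,
) -> TrainingSample:
    """Paste 0–4 distinct bank waveforms into a noise snippet.

    The waveform count follows the 50/30/12/6/2 % distribution; troughs are
    placed uniformly inside the scored 2–8 ms span, rejection-sampled until
    all pairwise spacings lie in [0.2 ms, 6 ms] (after 100 failed draws the
    count is reduced by one).  Waveforms extending past the window edge are
    truncated.  The same bank entry is never pasted twice into one sample.
    """
    if len(bank) == 0:
        raise ValueError("waveform bank is empty")
    fpms = sampling_rate / 1000.0
    margin = int(2 * fpms)
    span = int(6 * fpms)
    win = noise_snippet.shape[-1]
    count = int(rng.choice(5, p=PASTE_COUNT_PROBS))
    while count > len(bank):
        count = int(rng.choice(5, p=PASTE_COUNT_PROBS))
    troughs = None
    while count > 0 and troughs is None:
        troughs = _draw_troughs(rng, count, margin, span, fpms)
        if troughs is None:
            count -= 1
    trace = np.asarray(noise_snippet, dtype=np.float32).copy()
    gt: list[int] = []
    sources: list[int] = []
    if count > 0:
        picks = rng.choice(len(bank), size=count, replace=False)
        for t, k in zip(troughs, picks):
            entry = bank.entries[int(k)]
            w = entry.waveform
            start = t - entry.trough_index
            lo = max(0, start)
            hi = min(win, start + w.size)
            trace[lo:hi] += w[lo - start : hi - start]
            gt.append(int(t))
            sources.append(int(k))
    return TrainingSample(trace=trace, gt_troughs=gt, sources=sources)


# ------------------------------------------------------------------- epochs
@dataclass
class DetectorSource:
    """One source recording's contribution: waveform bank + noise pool."""

    name: str
    bank: WaveformBank
    noise_snippets: np.ndarray  # (n_electrodes, n_windows, win)

    def random_snippet(self, rng: np.random.Generator) -> np.ndarray:
        e = int(rng.integers(self.noise_snippets.shape[0]))
        w = int(rng.integers(self.noise_snippets.shape[1]))
        return self.noise_snippets[e, w]


def _merged_bank(sources: list[DetectorSource]) -> WaveformBank:
    bank = WaveformBank()
    for s in sources:
        bank.entries.extend(s.bank.entries)
    return bank


def build_epoch(
    sources: list[DetectorSource],
    val_index: int,
    sampling_rate: float,
    samples_per_waveform_train: int = 20,
    samples_per_waveform_val: int = 2,
    rng: np.random.Generator | None = None,
) -> tuple[list[TrainingSample], list[TrainingSample]]:
    """One training + validation epoch under the fold structure.

    The source at ``val_index`` is held out: its waveforms and noise build
    the validation samples only.  Training waveforms may be pasted into
    noise from any training source.  Raises if a source would leak across
    the split.
    """
    rng = rng or np.random.default_rng(0)
    if not (0 <= val_index < len(sources)):
        raise ValueError("val_index out of range")
    val_source = sources[val_index]
    train_sources = [s for i, s in enumerate(sources) if i != val_index]
    if any(s.name == val_source.name for s in train_sources):
        raise ValueError(
            f"fold leakage: source {val_source.name!r} appears in both splits"
        )
    if not train_sources:
        raise ValueError("need at least one training source")
    train_bank = _merged_bank(train_sources)
    if len(train_bank) == 0 or len(val_source.bank) == 0:
        raise ValueError("empty waveform bank in one of the splits")

    def make(n, bank, noise_sources):
        out = []
        for _ in range(n):
            src = noise_sources[int(rng.integers(len(noise_sources)))]
            out.append(
                synthesize_sample(
                    src.random_snippet(rng), bank, rng, sampling_rate
                )
            )
        return out

    n_train = samples_per_waveform_train * len(train_bank)
    n_val = samples_per_waveform_val * len(val_source.bank)
    train = make(n_train, train_bank, train_sources)
    val = make(n_val, val_source.bank, [val_source])
    return train, val
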