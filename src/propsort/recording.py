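"""Recording container, raw-binary I/O and amplitude primitives.

A recording is a frame-major signed-16-bit trace matrix (frames × electrodes)
with a sampling rate and a probe geometry.  On disk it is a flat ``int16``
binary next to a JSON metadata sidecar; nothing vendor specific.

Two amplitude primitives shared by every sorting stage live here:

* the *amplitude deviation* of a recording (median over electrodes of the
  interquartile range of the first 50 ms), used to rescale traces to the
  detector's training amplitude range, and
* the *standardized amplitude* of a single sample: its deviation from the
  median of the preceding 50 ms, divided by a floor-clipped robust noise
  scale ``max(0.5, MAD/0.6745)``.  The 50 ms baseline absorbs slow LFP
  offsets; the 0.5 floor keeps quiet electrodes from exploding the ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .probe import ProbeGeometry

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "amplitude_deviation",
    "scale_for_inference",
    "standardized_amplitude",
    "standardized_amplitudes",
]

MAD_TO_SD = 0.6745  # Φ⁻¹(0.75): scales a median absolute deviation to an SD
AMPLITUDE_WINDOW_MS = 50.0
MIN_AMPLITUDE_HISTORY_MS = 10.0
NOISE_FLOOR = 0.5


@dataclass
class Recording:
    """Raw extracellular traces plus sampling rate and probe geometry."""

    traces: np.ndarray  # (n_frames, n_electrodes), integer ADC units
    sampling_rate: float  # Hz
    geometry: ProbeGeometry

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (frames × electrodes)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.traces.shape[1] != self.geometry.n_electrodes:
            raise ValueError(
                f"traces have {self.traces.shape[1]} electrodes but geometry "
                f"has {self.geometry.n_electrodes}"
            )

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sampling_rate

    def frames_per_ms(self) -> float:
        return self.sampling_rate / 1000.0

    def ms_to_frames(self, ms: float) -> int:
        return int(round(ms * self.sampling_rate / 1000.0))


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write ``traces.bin`` (frame-major int16) + ``meta.json`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    traces = np.asarray(recording.traces, dtype=np.int16)
    traces.tofile(path / "traces.bin")
    meta = {
        "sampling_rate_hz": recording.sampling_rate,
        "n_electrodes": recording.n_electrodes,
        "geometry": recording.geometry.to_list(),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises ``ValueError`` when the binary length is inconsistent with the
    electrode count declared in the sidecar.
    """
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    n_electrodes = int(meta["n_electrodes"])
    raw = np.fromfile(path / "traces.bin", dtype=np.int16)
    if n_electrodes <= 0:
        raise ValueError("metadata must declare a positive electrode count")
    if raw.size % n_electrodes != 0:
        raise ValueError(
            f"binary holds {raw.size} samples, not a multiple of "
            f"{n_electrodes} electrodes"
        )
    traces = raw.reshape(-1, n_electrodes)
    geometry = ProbeGeometry.from_list(meta["geometry"])
    return Recording(traces, float(meta["sampling_rate_hz"]), geometry)


def amplitude_deviation(recording: Recording, strict: bool = True) -> float:
    """Median over electrodes of the IQR of the first 50 ms of each trace.

    With ``strict=False`` a recording shorter than 50 ms falls back to its
    full length (used when scaling very short traces for inference).
    """
    window = recording.ms_to_frames(AMPLITUDE_WINDOW_MS)
    if recording.n_frames < window:
        if strict or recording.n_frames == 0:
            raise ValueError(
                f"recording shorter than {AMPLITUDE_WINDOW_MS:g} ms "
                f"({recording.n_frames} < {window} frames)"
            )
        window = recording.n_frames
    head = recording.traces[:window].astype(np.float64)
    q75, q25 = np.percentile(head, [75, 25], axis=0)
    return float(np.median(q75 - q25))


def scale_for_inference(
    recording: Recording, training_amplitude_deviation: float
) -> np.ndarray:
    """Scale traces so their amplitude deviation matches the detector's
    training amplitude deviation.  Returns float32 traces."""
    dev = amplitude_deviation(recording, strict=False)
    if dev <= 0:
        raise ValueError("flat recording: amplitude deviation is zero")
    scale = training_amplitude_deviation / dev
    return recording.traces.astype(np.float32) * np.float32(scale)


def _window_bounds(frame: int, sampling_rate: float) -> tuple[int, int]:
    full = int(round(AMPLITUDE_WINDOW_MS * sampling_rate / 1000.0))
    minimum = int(round(MIN_AMPLITUDE_HISTORY_MS * sampling_rate / 1000.0))
    start = max(0, frame - full)
    if frame - start < minimum:
        raise ValueError(
            f"frame {frame} has less than {MIN_AMPLITUDE_HISTORY_MS:g} ms of "
            "history for amplitude standardization"
        )
    return start, frame


def standardized_amplitude(
    trace: np.ndarray, frame: int, sampling_rate: float
) -> float:
    """``(trace[frame] − A) / max(0.5, B)`` with A the median and B the
    MAD/0.6745 of the 50 ms window preceding (and excluding) ``frame``.

    Frames with less than 50 ms of history fall back to the available
    prefix, provided it covers at least 10 ms; shorter histories raise.
    """
    start, stop = _window_bounds(frame, sampling_rate)
    window = np.asarray(trace[start:stop], dtype=np.float64)
    a = np.median(window)
    b = np.median(np.abs(window - a)) / MAD_TO_SD
    return float((float(trace[frame]) - a) / max(NOISE_FLOOR, b))


def standardized_amplitudes(
    trace: np.ndarray, frames: np.ndarray, sampling_rate: float
) -> np.ndarray:
    """Vectorized :func:`standardized_amplitude` over many detection frames.

    Frames with insufficient history yield NaN instead of raising, so batch
    callers can drop them.  Full-history frames are processed as one
    batched median; short-history frames near the recording start fall
    back to the scalar routine.
    """
    frames = np.asarray(frames, dtype=np.int64)
    out = np.full(frames.shape, np.nan)
    if frames.size == 0:
        return out
    full = int(round(AMPLITUDE_WINDOW_MS * sampling_rate / 1000.0))
    trace = np.asarray(trace)
    ok = (frames >= full) & (frames < trace.shape[0])
    if np.any(ok):
        f_ok = frames[ok]
        win = trace[
            f_ok[:, None] + np.arange(-full, 0)[None, :]
        ].astype(np.float64)
        a = np.median(win, axis=1)
        b = np.median(np.abs(win - a[:, None]), axis=1) / MAD_TO_SD
        out[ok] = (trace[f_ok].astype(np.float64) - a) / np.maximum(
            NOISE_FLOOR, b
        )
    for i in np.flatnonzero(~ok):
        try:
            out[i] = standardized_amplitude(trace, int(frames[i]), sampling_rate)
        except (ValueError, IndexError):
            pass
    return out
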