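"""Detector inference: offline window tiling, streaming windows, event
extraction from score traces, and the gradient-ascent probe.

Offline mode tiles 10 ms windows with a 6 ms stride so the scored 2–8 ms
interiors abut: every frame at least 2 ms from either end of the recording
receives exactly one score.  Streaming mode advances 10 ms windows by 5 ms;
overlapping interiors are resolved by a deterministic ownership rule (a
frame belongs to the earliest window whose scored interior contains it),
which both minimizes latency and makes the emitted stream independent of
chunk boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy.ndimage import maximum_filter1d

from ..recording import Recording, scale_for_inference
from .net import SpikeDetector, preprocess_window

__all__ = [
    "DetectionScores",
    "infer_offline",
    "infer_streaming",
    "detect_events",
    "gradient_ascent_probe",
]


@dataclass
class DetectionScores:
    """Per-electrode, per-frame trough-likelihood scores in [0, 100].

    ``scores`` is aligned frame-for-frame with the source recording; frames
    outside ``[valid_start, valid_end)`` (the first/last 2 ms) carry no
    prediction and are stored as 0.
    """

    scores: np.ndarray  # (n_frames, n_electrodes) float32
    valid_start: int
    valid_end: int
    sampling_rate: float


def _score_windows(
    detector: SpikeDetector, windows: np.ndarray, batch: int = 4096
) -> np.ndarray:
    """Score a stack of raw float windows (N, input_frames), chunked."""
    out = []
    for i in range(0, windows.shape[0], batch):
        block = preprocess_window(windows[i : i + batch])
        out.append(detector.forward(block).astype(np.float32))
    return np.concatenate(out, axis=0) if out else np.empty((0, 0), np.float32)


def infer_offline(
    recording: Recording,
    detector: SpikeDetector,
    training_amplitude_deviation: float,
) -> DetectionScores:
    """Score every interior frame of a recording exactly once.

    Traces are first rescaled by the training amplitude deviation over the
    recording's own amplitude deviation; each 10 ms window is then median
    subtracted independently, exactly as during training.
    """
    cfg = detector.config
    if recording.sampling_rate != cfg.sampling_rate:
        raise ValueError(
            f"recording at {recording.sampling_rate} Hz does not match "
            f"detector at {cfg.sampling_rate} Hz"
        )
    n_in, n_out, margin = cfg.input_frames, cfg.output_frames, cfg.margin_frames
    n_frames = recording.n_frames
    if n_frames < n_in:
        raise ValueError("recording shorter than one 10 ms window")
    traces = scale_for_inference(recording, training_amplitude_deviation)
    scores = np.zeros((n_frames, recording.n_electrodes), dtype=np.float32)

    starts = list(range(0, n_frames - n_in + 1, n_out))
    tail_start = n_frames - n_in
    if tail_start > starts[-1]:
        starts.append(tail_start)  # partial-stride window for the tail

    for e in range(recording.n_electrodes):
        col = traces[:, e]
        wins = np.stack([col[s : s + n_in] for s in starts])
        sc = _score_windows(detector, wins)
        prev_end = margin
        for w, s in enumerate(starts):
            lo = max(s + margin, prev_end)
            hi = s + n_in - margin
            if hi <= lo:
                continue
            scores[lo:hi, e] = sc[w, lo - s - margin : hi - s - margin]
            prev_end = hi
    return DetectionScores(
        scores=scores,
        valid_start=margin,
        valid_end=n_frames - margin,
        sampling_rate=recording.sampling_rate,
    )


def infer_streaming(
    chunk_source: Iterable[tuple[int, np.ndarray]],
    detector: SpikeDetector,
    inference_scale: float,
    hop_ms: float = 5.0,
) -> Iterator[tuple[int, np.ndarray]]:
    """Stream scores over chunked traces.

    ``chunk_source`` yields ``(start_frame, chunk)`` with chunk shaped
    (frames, n_electrodes), in frame order and gap-free.  Yields
    ``(start_frame, score_block)`` covering each newly owned span, identical
    to what offline inference would produce for the same window content.
    ``inference_scale`` is the multiplicative trace scaling (training
    amplitude deviation / recording amplitude deviation), normally taken
    from the pre-recording since a live stream cannot be rescanned.
    """
    cfg = detector.config
    n_in, margin = cfg.input_frames, cfg.margin_frames
    hop = int(round(hop_ms * cfg.sampling_rate / 1000.0))
    buf: np.ndarray | None = None
    buf_start = 0  # absolute frame of buf[0]
    next_frame = 0
    next_window = 0  # index of the next 10 ms window to process
    for start, chunk in chunk_source:
        chunk = np.asarray(chunk)
        if start != next_frame:
            raise ValueError(
                f"out-of-order chunk: expected frame {next_frame}, got {start}"
            )
        next_frame = start + chunk.shape[0]
        scaled = chunk.astype(np.float32) * np.float32(inference_scale)
        buf = scaled if buf is None else np.concatenate([buf, scaled], axis=0)
        while next_window * hop + n_in <= buf_start + buf.shape[0]:
            s = next_window * hop
            wins = buf[s - buf_start : s - buf_start + n_in].T  # (elec, n_in)
            sc = _score_windows(detector, wins)  # (elec, n_out)
            if next_window == 0:
                own_lo = s + margin
            else:
                own_lo = (next_window - 1) * hop + n_in - margin
            own_hi = s + n_in - margin
            off = own_lo - (s + margin)
            yield own_lo, sc[:, off : off + (own_hi - own_lo)].T.copy()
            next_window += 1
            # drop buffer history no longer needed by any future window
            keep_from = next_window * hop
            if keep_from > buf_start:
                buf = buf[keep_from - buf_start :]
                buf_start = keep_from


def detect_events(
    score_trace: np.ndarray,
    threshold: float,
    nms_radius: int,
    offset: int = 0,
) -> np.ndarray:
    """Detection events from one electrode's score trace.

    An event is a local maximum of the score strictly above ``threshold``,
    with non-maximum suppression over ±``nms_radius`` frames (ties within a
    plateau keep the earliest frame).  Returns absolute frames
    (``offset`` + index).
    """
    s = np.asarray(score_trace)
    if s.size == 0:
        return np.empty(0, dtype=np.int64)
    mf = maximum_filter1d(s, size=2 * nms_radius + 1, mode="constant")
    cand = np.flatnonzero((s > threshold) & (s >= mf))
    kept: list[int] = []
    last = -(10 * nms_radius + 10)
    for f in cand:
        if f - last > nms_radius:
            kept.append(int(f))
            last = f
    return np.asarray(kept, dtype=np.int64) + offset


def gradient_ascent_probe(
    detector: SpikeDetector,
    noise_window: np.ndarray,
    n_iterations: int = 200,
    step: float = 1.0,
    target_score: float = 99.0,
) -> np.ndarray:
    """Gradient ascent on an input noise window.

    Perturbs the window so the detector's center output frame approaches
    certainty, revealing the waveform shape the detector has learned to
    look for.  Returns the optimized window (the input is not modified).
    """
    x = np.asarray(noise_window, dtype=np.float32).copy()
    center = detector.config.output_frames // 2
    for _ in range(n_iterations):
        logits, acts = detector.forward_train(preprocess_window(x))
        p = 1.0 / (1.0 + np.exp(-float(logits[0, center])))
        if 100.0 * p >= target_score:
            break
        dlogits = np.zeros_like(logits)
        dlogits[0, center] = 1.0  # ascend the center frame's logit
        _, dx = detector.backward(acts, dlogits)
        g = dx[0]
        norm = float(np.max(np.abs(g)))
        if norm == 0:
            break
        x += step * (g / norm).astype(np.float32)
    return x
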