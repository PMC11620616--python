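"""Pipeline drivers: offline sorting and online (streaming) sorting.

Offline mode scores the whole recording, detects propagation sequences,
reassigns spikes, merges over-split sequences and reassigns again — the
result is the final spike trains.

Online mode assumes the sequences were detected in a *pre-recording* with
the identical electrode configuration.  A 10 ms window is scored every
5 ms (the overlap covers spikes falling near window seams); detection
events are finalized incrementally with a short look-back buffer, matched
against the frozen sequence metrics, dedup-resolved within the 0.2 ms
window, and emitted with a per-event latency breakdown (biological wait,
detection compute, sorting compute).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .assign import (
    assign_spike,
    merge_all,
    reassign_all,
    resolve_duplicates,
    spike_features,
    _difference_score,
)
from .detector.infer import DetectionScores, detect_events, infer_offline, infer_streaming
from .detector.net import SpikeDetector
from .params import Params
from .probe import ProbeGeometry
from .recording import Recording, amplitude_deviation
from .sequences import PropagationSequence, detect_sequences

__all__ = [
    "SortedEvent",
    "OfflineResult",
    "run_offline",
    "run_streaming",
    "replay_chunks",
    "latency_report",
]


@dataclass
class SortedEvent:
    sequence_id: int
    trough_frame: int
    emission_frame: int  # stream position when the event was decidable
    emission_time: float  # wall-clock (monotonic) seconds at emission
    biological_ms: float  # waveform + propagation + windowing wait
    detection_ms: float  # CNN compute attributed to this event's tick
    sorting_ms: float  # assignment/dedup compute for this event's tick

    @property
    def total_ms(self) -> float:
        return self.biological_ms + self.detection_ms + self.sorting_ms


@dataclass
class OfflineResult:
    sequences: list[PropagationSequence]
    spike_trains: dict[int, np.ndarray]
    scores: DetectionScores
    context: object


def run_offline(
    recording: Recording,
    detector: SpikeDetector,
    training_amplitude_deviation: float,
    params: Params,
    seed: int = 0,
) -> OfflineResult:
    """Full offline pipeline; deterministic under a fixed seed."""
    scores = infer_offline(recording, detector, training_amplitude_deviation)
    sequences, ctx = detect_sequences(recording, scores, params, seed)
    if sequences:
        # first reassignment: duplicates resolved within same-root groups
        sequences, _ = reassign_all(
            ctx, sequences, mutually_inner_dedup=False, update_metrics=True
        )
    if sequences:
        sequences = merge_all(ctx, sequences)
    trains: dict[int, np.ndarray] = {}
    if sequences:
        sequences, trains = reassign_all(
            ctx, sequences, mutually_inner_dedup=True, update_metrics=True
        )
    return OfflineResult(sequences, trains, scores, ctx)


def replay_chunks(
    recording: Recording, chunk_frames: int
) -> Iterator[tuple[int, np.ndarray]]:
    """Replay a recording as a chunked stream."""
    for s in range(0, recording.n_frames, chunk_frames):
        yield s, recording.traces[s : s + chunk_frames]


class _Growing:
    """Append-only 2-D buffer with geometric reallocation."""

    def __init__(self, n_cols: int, dtype):
        self.data = np.zeros((1 << 16, n_cols), dtype=dtype)
        self.n = 0

    def append(self, block: np.ndarray, at: int | None = None):
        start = self.n if at is None else at
        end = start + block.shape[0]
        while end > self.data.shape[0]:
            self.data = np.vstack(
                [self.data, np.zeros_like(self.data)]
            )
        self.data[start:end] = block
        self.n = max(self.n, end)


@dataclass
class _StreamView:
    """Duck-typed stand-in for SortingContext over growing buffers."""

    scores_buf: _Growing
    traces_buf: _Growing
    sampling_rate: float
    geometry: ProbeGeometry
    params: Params

    @property
    def scores(self):
        view = self

        class _S:
            scores = view.scores_buf.data

        return _S

    @property
    def recording(self):
        view = self

        class _R:
            traces = view.traces_buf.data
            sampling_rate = view.sampling_rate

        return _R

    def frames(self, ms: float) -> int:
        return int(round(ms * self.sampling_rate / 1000.0))


class _EventTracker:
    """Incremental local-max + NMS event extraction on one electrode.

    Produces exactly the events a full-trace pass would, independent of
    chunking: a frame is a candidate once its ±nms context is fully
    scored, and greedy suppression state persists across ticks.
    """

    def __init__(self, threshold: float, nms: int):
        self.threshold = threshold
        self.nms = nms
        self.done = 0  # frames strictly below this have been examined
        self.last_kept = -(10**9)
        self.finalized: list[int] = []

    def advance(self, scores_col: np.ndarray, coverage: int) -> list[int]:
        hi = coverage - self.nms
        new = []
        r = self.nms
        while self.done < hi:
            f = self.done
            s = scores_col[f]
            if s > self.threshold:
                lo = max(0, f - r)
                window = scores_col[lo : f + r + 1]
                if s >= window.max() and f - self.last_kept > r:
                    # earliest frame of a plateau wins
                    if not np.any(window[: f - lo] == s):
                        self.last_kept = f
                        new.append(f)
            self.done += 1
        self.finalized.extend(new)
        return new


def run_streaming(
    chunk_source: Iterable[tuple[int, np.ndarray]],
    detector: SpikeDetector,
    sequences: list[PropagationSequence],
    params: Params,
    geometry: ProbeGeometry,
    inference_scale: float,
) -> Iterator[SortedEvent]:
    """Sort a live stream against frozen sequence metrics.

    Events are emitted in nondecreasing trough order within a bounded
    reordering horizon; an event whose propagation period spills past the
    current window is decided at a later tick, never dropped.
    """
    cfg = detector.config
    rate = cfg.sampling_rate
    fpms = rate / 1000.0
    nms = int(round(0.5 * fpms))
    w_prop = int(round(params.propagation_window_ms * fpms))
    dedup = int(round(params.dedup_window_ms * fpms))
    n_elec = geometry.n_electrodes
    for s in sequences:
        if s.median_score.size != n_elec:
            raise ValueError(
                "sequence metrics do not match the electrode configuration"
            )
    scores_buf = _Growing(n_elec, np.float32)
    traces_buf = _Growing(n_elec, np.float32)
    view = _StreamView(scores_buf, traces_buf, rate, geometry, params)

    roots: dict[int, list[PropagationSequence]] = {}
    for s in sequences:
        roots.setdefault(s.root_electrode, []).append(s)
    trackers = {
        e: _EventTracker(params.stringent_threshold, nms) for e in roots
    }
    pending: list[dict] = []  # candidate assignments awaiting dedup horizon
    accepted_tail: list[dict] = []
    min_history = int(round(10.0 * fpms))  # amplitude standardization floor

    def tee(source):
        for start, chunk in source:
            chunk = np.asarray(chunk)
            if chunk.shape[1] != n_elec:
                raise ValueError("chunk electrode count mismatch")
            traces_buf.append(chunk.astype(np.float32), at=start)
            yield start, chunk

    lookahead = w_prop + dedup + 1
    score_stream = infer_streaming(tee(chunk_source), detector, inference_scale)
    for own_lo, block in score_stream:
        t_tick = time.perf_counter()
        scores_buf.append(block.astype(np.float32), at=own_lo)
        coverage = own_lo + block.shape[0]
        t_detect = time.perf_counter()
        # finalize candidate root events whose full context is available
        new_entries = []
        for e, tr in trackers.items():
            for f in tr.advance(scores_buf.data[:, e], coverage):
                if f < min_history:
                    continue
                for seq in roots[e]:
                    new_entries.append(
                        {"time": f, "root": e, "seq": seq, "tick": coverage}
                    )
        t_assign = time.perf_counter()
        # a candidate is decidable once scores cover its propagation period
        for c in new_entries:
            pending.append(c)
        pending.sort(key=lambda c: c["time"])
        emitted = []
        while pending:
            horizon_ok = pending[0]["time"] + lookahead <= coverage
            if not horizon_ok:
                break
            # gather the maximal chain of near-coincident candidates
            chain = [pending.pop(0)]
            while pending and (
                pending[0]["time"] - chain[-1]["time"] <= dedup
                and pending[0]["time"] + lookahead <= coverage
            ):
                chain.append(pending.pop(0))
            if pending and pending[0]["time"] - chain[-1]["time"] <= dedup:
                # chain not yet complete; put it back and wait
                pending = chain + pending
                break
            entries = []
            for c in chain:
                feat = spike_features(view, c["seq"], c["time"])
                if not assign_spike(view, c["seq"], feat):
                    continue
                try:
                    score = _difference_score(view, c["seq"], feat)
                except ValueError:
                    continue
                entries.append(
                    {
                        "sequence_id": c["seq"].sequence_id,
                        "root": c["root"],
                        "time": c["time"],
                        "score": score,
                    }
                )
            kept = resolve_duplicates(
                entries, params, dedup, geometry, mutually_inner=True
            )
            emitted.extend(kept)
        t_done = time.perf_counter()
        for c in emitted:
            # the window whose interior scores t+0.5ms ends at:
            decid = c["time"] + lookahead
            bio = (decid - c["time"]) / fpms + (cfg.margin_frames / fpms)
            yield SortedEvent(
                sequence_id=c["sequence_id"],
                trough_frame=c["time"],
                emission_frame=coverage,
                emission_time=t_done,
                biological_ms=bio,
                detection_ms=1000.0 * (t_detect - t_tick),
                sorting_ms=1000.0 * (t_done - t_assign),
            )
        accepted_tail = (accepted_tail + emitted)[-32:]


def latency_report(events: list[SortedEvent]) -> dict:
    """Distribution summaries of per-event latency and its components."""
    if not events:
        return {"n_events": 0}
    bio = np.array([e.biological_ms for e in events])
    det = np.array([e.detection_ms for e in events])
    srt = np.array([e.sorting_ms for e in events])
    tot = bio + det + srt

    def summ(x):
        return {
            "mean": float(x.mean()),
            "median": float(np.median(x)),
            "p95": float(np.percentile(x, 95)),
        }

    return {
        "n_events": len(events),
        "total_ms": summ(tot),
        "biological_ms": summ(bio),
        "detection_ms": summ(det),
        "sorting_ms": summ(srt),
    }
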