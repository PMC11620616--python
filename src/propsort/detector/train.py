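"""Detector training, threshold calibration and detection evaluation.

Training follows the regime the architecture was tuned for: plain
stochastic gradient descent with momentum 0.85 at batch size 1, per-frame
binary cross-entropy against a target that is 1 exactly at ground-truth
trough frames and 0 elsewhere.  The learning rate drops by ×0.4 whenever
the validation loss stalls for more than five epochs, training stops after
ten stalled epochs, and the weights from the best validation epoch are
returned.

Two thresholds are calibrated on validation data: a *stringent* threshold
at the F1 optimum (used for root detections, precision-first) and a *loose*
threshold chosen so validation recall exceeds precision by about 15
percentage points (used for supporting detections, recall-first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..matching import greedy_match
from .infer import detect_events
from .net import SpikeDetector, _sigmoid, preprocess_window

__all__ = [
    "Thresholds",
    "TrainingScheduler",
    "Hyperparams",
    "train_detector",
    "calibrate_thresholds",
    "evaluate_detection",
    "rms_threshold_events",
]

MATCH_TOLERANCE_MS = 0.4


@dataclass(frozen=True)
class Thresholds:
    stringent: float
    loose: float

    def __post_init__(self):
        if not (0 < self.loose <= self.stringent < 100):
            raise ValueError("need 0 < loose ≤ stringent < 100")


@dataclass
class Hyperparams:
    learning_rate: float = 0.000776  # 0.0002 for the Neuropixels profile
    momentum: float = 0.85
    lr_factor: float = 0.4
    lr_patience: int = 5  # stalled epochs tolerated before reducing
    lr_min_delta: float = 0.0001  # 0.01 for the Neuropixels profile
    stop_patience: int = 10
    stop_min_delta: float = 0.01
    max_epochs: int = 100
    shuffle_seed: int = 0


class TrainingScheduler:
    """Validation-loss bookkeeping: lr reductions, early stop, best epoch.

    ``update`` returns ``(reduce_lr, stop)``.  A reduction fires on the
    first epoch *beyond* the patience window without the required
    improvement, then the stall counter restarts.
    """

    def __init__(self, hyper: Hyperparams):
        self.h = hyper
        self.best_val = np.inf
        self.best_epoch = -1
        self._lr_best = np.inf
        self._lr_stall = 0
        self._stop_best = np.inf
        self._stop_stall = 0
        self.epoch = -1

    def update(self, val_loss: float) -> tuple[bool, bool]:
        self.epoch += 1
        if val_loss < self.best_val:
            self.best_val = val_loss
            self.best_epoch = self.epoch
        reduce_lr = False
        if val_loss <= self._lr_best - self.h.lr_min_delta:
            self._lr_best = val_loss
            self._lr_stall = 0
        else:
            self._lr_stall += 1
            if self._lr_stall > self.h.lr_patience:
                reduce_lr = True
                self._lr_stall = 0
                self._lr_best = min(self._lr_best, val_loss)
        if val_loss <= self._stop_best - self.h.stop_min_delta:
            self._stop_best = val_loss
            self._stop_stall = 0
        else:
            self._stop_stall += 1
        stop = self._stop_stall >= self.h.stop_patience
        return reduce_lr, stop


def _targets(sample, cfg) -> np.ndarray:
    y = np.zeros(cfg.output_frames, dtype=np.float32)
    for t in sample.gt_troughs:
        idx = int(t) - cfg.margin_frames
        if 0 <= idx < cfg.output_frames:
            y[idx] = 1.0
    return y


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-7
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train_detector(
    detector: SpikeDetector,
    train_set: list,
    val_set: list,
    hyper: Hyperparams | None = None,
    verbose: bool = False,
):
    """Train in place; returns ``(detector, history)``.

    ``train_set`` / ``val_set`` are lists of training samples (10 ms trace +
    ground-truth trough frames).  The detector's weights are replaced by
    those of the best validation epoch; ``history`` is a DataFrame with one
    row per epoch (train_loss, val_loss, lr).
    """
    if not train_set or not val_set:
        raise ValueError("training and validation sets must be non-empty")
    hyper = hyper or Hyperparams()
    cfg = detector.config
    rng = np.random.default_rng(hyper.shuffle_seed)
    lr = hyper.learning_rate
    vel = [
        (np.zeros_like(w), np.zeros_like(b)) for w, b in detector.weights
    ]
    sched = TrainingScheduler(hyper)
    best_weights = [(w.copy(), b.copy()) for w, b in detector.weights]
    rows = []

    xs_train = [preprocess_window(s.trace) for s in train_set]
    ys_train = [_targets(s, cfg) for s in train_set]
    xs_val = np.stack([preprocess_window(s.trace) for s in val_set])
    ys_val = np.stack([_targets(s, cfg) for s in val_set])

    for epoch in range(hyper.max_epochs):
        order = rng.permutation(len(xs_train))
        total = 0.0
        for i in order:
            logits, acts = detector.forward_train(xs_train[i])
            p = _sigmoid(logits)
            y = ys_train[i][None, :]
            total += _bce(p, y)
            dlogits = (p - y) / y.shape[1]  # d(mean BCE)/dz
            grads, _ = detector.backward(acts, dlogits)
            new_w = []
            for (w, b), (vw, vb), (gw, gb) in zip(
                detector.weights, vel, grads
            ):
                vw *= hyper.momentum
                vw -= lr * gw
                vb *= hyper.momentum
                vb -= lr * gb
                new_w.append((w + vw, b + vb))
            detector.weights = new_w
            vel = [(vw, vb) for (_, _), (vw, vb) in zip(new_w, vel)]
        train_loss = total / len(xs_train)

        val_p = _sigmoid(detector.forward_logits(xs_val))
        val_loss = _bce(val_p, ys_val)

        improved = val_loss < sched.best_val
        reduce_lr, stop = sched.update(val_loss)
        if improved or sched.best_epoch == epoch:
            best_weights = [(w.copy(), b.copy()) for w, b in detector.weights]
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "lr": lr}
        )
        if verbose:
            print(f"epoch {epoch}: train {train_loss:.4f} val {val_loss:.4f} lr {lr:.2e}")
        if reduce_lr:
            lr *= hyper.lr_factor
        if stop:
            break
    detector.weights = best_weights
    return detector, pd.DataFrame(rows)


def _sample_events(scores: np.ndarray, threshold: float, nms: int) -> np.ndarray:
    return detect_events(scores, threshold, nms)


def evaluate_detection(
    detected: np.ndarray,
    gt_troughs: np.ndarray,
    sampling_rate: float,
    tolerance_ms: float = MATCH_TOLERANCE_MS,
) -> dict:
    """Precision/recall/F1 and per-match timing deviations (frames).

    Detections within 0.4 ms of a true trough count as true positives;
    matching is greedy one-to-one nearest-first.
    """
    tol = tolerance_ms * sampling_rate / 1000.0
    detected = np.sort(np.asarray(detected, dtype=np.float64))
    gt = np.sort(np.asarray(gt_troughs, dtype=np.float64))
    pairs = greedy_match(detected, gt, tol)
    n_match = pairs.shape[0]
    precision = n_match / detected.size if detected.size else 1.0
    recall = n_match / gt.size if gt.size else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    deviations = (
        np.abs(detected[pairs[:, 0]] - gt[pairs[:, 1]])
        if n_match
        else np.empty(0)
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_matches": n_match,
        "timing_deviations": deviations,
    }


def _pooled_pr(detector: SpikeDetector, samples: list, threshold: float):
    cfg = detector.config
    nms = max(1, int(round(0.5 * cfg.frames_per_ms)))
    tol = MATCH_TOLERANCE_MS * cfg.frames_per_ms
    windows = np.stack([preprocess_window(s.trace) for s in samples])
    scores = detector.forward(windows)
    tp = fp = fn = 0
    for i, s in enumerate(samples):
        det = detect_events(scores[i], threshold, nms, offset=cfg.margin_frames)
        gt = np.sort(np.asarray(s.gt_troughs, dtype=np.float64))
        pairs = greedy_match(det.astype(np.float64), gt, tol)
        tp += pairs.shape[0]
        fp += det.size - pairs.shape[0]
        fn += gt.size - pairs.shape[0]
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return precision, recall


def calibrate_thresholds(
    detector: SpikeDetector,
    val_samples: list,
    thresholds: np.ndarray | None = None,
    recall_margin: float = 0.15,
) -> Thresholds:
    """Sweep score thresholds on validation samples.

    Stringent = the F1-optimal threshold (ties broken towards the highest
    threshold, favouring precision).  Loose = the threshold, at most the
    stringent one, where recall − precision is closest to ``recall_margin``.
    """
    if not any(len(s.gt_troughs) for s in val_samples):
        raise ValueError("validation set contains no spikes")
    if thresholds is None:
        thresholds = np.arange(2.5, 100.0, 2.5)
    stats = []
    for thr in thresholds:
        p, r = _pooled_pr(detector, val_samples, thr)
        f1 = 2 * p * r / (p + r) if (p + r) else 0.0
        stats.append((thr, p, r, f1))
    best_f1 = max(s[3] for s in stats)
    stringent = max(t for t, _, _, f1 in stats if f1 == best_f1)
    eligible = [s for s in stats if s[0] <= stringent]
    loose = min(
        eligible, key=lambda s: (abs((s[2] - s[1]) - recall_margin), -s[0])
    )[0]
    return Thresholds(stringent=float(stringent), loose=float(loose))


def rms_threshold_events(
    trace: np.ndarray, sampling_rate: float, factor: float = 5.0
) -> np.ndarray:
    """Baseline threshold detector: troughs crossing −factor × RMS.

    The classical alternative to the learned detector; used for the
    directional recall comparison.
    """
    x = np.asarray(trace, dtype=np.float64)
    x = x - np.median(x)
    rms = np.sqrt(np.mean(x**2))
    nms = max(1, int(round(0.5 * sampling_rate / 1000.0)))
    if rms == 0:
        return np.empty(0, dtype=np.int64)
    return detect_events(-x, factor * rms, nms)
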