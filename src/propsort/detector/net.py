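"""Per-electrode convolutional trough detector.

The network is a small fully-convolutional 1-D CNN: three hidden
convolutional layers (rectifier nonlinearity) and one output convolution
followed by a sigmoid whose output is scaled to [0, 100].  All kernels span
one millisecond of raw data plus one frame, with stride 1, so after four
'valid' convolutions a 10 ms input window maps onto the detector's scored
span: the frames between 2 and 8 ms of the window.  Each scored frame sees
exactly ±2 ms of raw context.  At 20 kHz that is a 200-frame input, kernel
21 and a 120-frame output; at 30 kHz, 300 / 31 / 180.

Implemented directly on numpy: convolutions are lowered to im2col + GEMM in
float32, which is fast enough for both sample-level training (batch size 1)
and chunked full-recording inference on a CPU.  Inputs are stored as int16
and cast to floating point on entry; accumulation is float32 throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["DetectorConfig", "SpikeDetector", "preprocess_window"]

DEFAULT_N_FILTERS = 50


@dataclass(frozen=True)
class DetectorConfig:
    """Architecture arithmetic for a given sampling rate.

    ``n_filters`` is the hidden width (50 in the reference architecture;
    smaller widths are useful for quick CPU runs and keep every other
    architectural rule intact).
    """

    sampling_rate: float
    n_filters: int = DEFAULT_N_FILTERS

    def __post_init__(self) -> None:
        if self.frames_per_ms != int(self.frames_per_ms):
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz does not yield an "
                "integer number of frames per millisecond"
            )
        if self.n_filters < 1:
            raise ValueError("n_filters must be positive")

    @property
    def frames_per_ms(self) -> float:
        return self.sampling_rate / 1000.0

    @property
    def input_frames(self) -> int:
        """Frames in the 10 ms input window."""
        return int(10 * self.frames_per_ms)

    @property
    def output_frames(self) -> int:
        """Frames in the scored 2–8 ms span of the window."""
        return int(6 * self.frames_per_ms)

    @property
    def kernel_frames(self) -> int:
        """Frames in 1 ms of raw data, plus one."""
        return int(self.frames_per_ms) + 1

    @property
    def margin_frames(self) -> int:
        """Unscored margin (2 ms) on either side of a window."""
        return int(2 * self.frames_per_ms)

    @property
    def n_layers(self) -> int:
        return 4

    def layer_shapes(self) -> list[tuple[int, int, int]]:
        """(out_channels, in_channels, kernel) per layer."""
        f, k = self.n_filters, self.kernel_frames
        return [(f, 1, k), (f, f, k), (f, f, k), (1, f, k)]

    @property
    def n_parameters(self) -> int:
        return sum(o * i * k + o for o, i, k in self.layer_shapes())


def preprocess_window(raw_window: np.ndarray) -> np.ndarray:
    """Cast a raw window to float32 and subtract its median.

    Median subtraction removes the slow, high-amplitude LFP offset so the
    detector sees a zero-centred trace regardless of the local field.
    Accepts (..., frames); the median is taken along the last axis.
    """
    w = np.asarray(raw_window, dtype=np.float32)
    return w - np.median(w, axis=-1, keepdims=True).astype(np.float32)


@njit(fastmath=True, cache=False)
def _conv_kernel(x, w, bias):
    """Direct valid 1-D convolution; the time loop vectorizes well."""
    n_b, n_c, n_t = x.shape
    n_o, _, n_k = w.shape
    tp = n_t - n_k + 1
    y = np.empty((n_b, n_o, tp), dtype=np.float32)
    for bi in range(n_b):
        for o in range(n_o):
            acc = y[bi, o]
            for t in range(tp):
                acc[t] = bias[o]
            for c in range(n_c):
                xc = x[bi, c]
                for k in range(n_k):
                    wv = w[o, c, k]
                    for t in range(tp):
                        acc[t] += wv * xc[t + k]
    return y


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 1-D convolution. x: (B, C, T); w: (O, C, K) → (B, O, T−K+1)."""
    return _conv_kernel(
        np.ascontiguousarray(x, dtype=np.float32),
        np.ascontiguousarray(w, dtype=np.float32),
        np.ascontiguousarray(b, dtype=np.float32),
    )


def _conv_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a valid 1-D convolution.

    Returns (dx, dw, db) for x: (B, C, T), w: (O, C, K), dy: (B, O, T').
    """
    k = w.shape[2]
    xw = sliding_window_view(x, k, axis=2)  # (B, C, T', K)
    dw = np.einsum("bot,bctk->ock", dy, xw, optimize=True)  # (O, C, K)
    db = dy.sum(axis=(0, 2))
    pad = np.zeros(dy.shape[:2] + (k - 1,), dtype=dy.dtype)
    dyp = np.concatenate([pad, dy, pad], axis=2)
    dyw = sliding_window_view(dyp, k, axis=2)  # (B, O, T, K)
    wf = w[:, :, ::-1]
    dx = np.einsum("bosk,ock->bcs", dyw, wf, optimize=True)
    return dx, dw, db


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SpikeDetector:
    """The trough-likelihood CNN: weights, forward pass and serialization.

    ``forward`` accepts a batch of preprocessed windows (B, T) with
    T ≥ ``config.input_frames`` and returns scores (B, T − 4·(K−1)) in
    [0, 100]; being fully convolutional, longer inputs score longer interior
    spans with identical per-frame arithmetic.
    """

    def __init__(self, config: DetectorConfig, weights=None, seed: int = 0):
        self.config = config
        if weights is None:
            rng = np.random.default_rng(seed)
            weights = []
            for o, c, k in config.layer_shapes():
                fan_in = c * k
                std = np.sqrt(2.0 / fan_in)
                weights.append(
                    (
                        rng.normal(0.0, std, size=(o, c, k)).astype(np.float32),
                        np.zeros(o, dtype=np.float32),
                    )
                )
        self.weights = weights

    # ------------------------------------------------------------------ API
    @property
    def n_parameters(self) -> int:
        return self.config.n_parameters

    def forward(self, windows: np.ndarray) -> np.ndarray:
        """Scores in [0, 100] for a batch of preprocessed windows (B, T)."""
        return 100.0 * _sigmoid(self.forward_logits(windows))

    def forward_logits(self, windows: np.ndarray) -> np.ndarray:
        x = np.asarray(windows, dtype=np.float32)[:, None, :]
        for i, (w, b) in enumerate(self.weights):
            x = _conv_forward(x, w, b)
            if i < len(self.weights) - 1:
                np.maximum(x, 0.0, out=x)
        return x[:, 0, :]

    def forward_train(self, window: np.ndarray):
        """Forward pass retaining activations for backprop (batch of 1+)."""
        x = np.asarray(window, dtype=np.float32)
        if x.ndim == 1:
            x = x[None, :]
        x = x[:, None, :]
        acts = [x]
        for i, (w, b) in enumerate(self.weights):
            x = _conv_forward(x, w, b)
            if i < len(self.weights) - 1:
                np.maximum(x, 0.0, out=x)
            acts.append(x)
        return acts[-1][:, 0, :], acts

    def backward(self, acts, dlogits: np.ndarray):
        """Gradients of a scalar loss w.r.t. weights and the input window.

        ``dlogits``: (B, T_out) gradient at the output layer's
        pre-sigmoid activations.  Returns (grads, dinput) with grads a list
        of (dW, db) matching ``self.weights``.
        """
        dy = np.asarray(dlogits, dtype=np.float32)[:, None, :]
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.weights)
        for i in range(len(self.weights) - 1, -1, -1):
            w, _ = self.weights[i]
            x_in = acts[i]
            dx, dw, db = _conv_backward(x_in, w, dy)
            grads[i] = (dw, db)
            if i > 0:
                dx[acts[i] <= 0] = 0.0  # ReLU gate of the layer below
            dy = dx
        return grads, dy[:, 0, :]

    # ------------------------------------------------------------ persistence
    def save(self, path: str | Path, training_amplitude_deviation: float | None = None):
        path = Path(path)
        arrays = {}
        for i, (w, b) in enumerate(self.weights):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        header = {
            "sampling_rate": self.config.sampling_rate,
            "n_filters": self.config.n_filters,
            "training_amplitude_deviation": training_amplitude_deviation,
        }
        arrays["header"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path):
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            config = DetectorConfig(
                sampling_rate=header["sampling_rate"],
                n_filters=header["n_filters"],
            )
            weights = []
            i = 0
            while f"w{i}" in data:
                weights.append((data[f"w{i}"], data[f"b{i}"]))
                i += 1
        det = cls(config, weights=weights)
        return det, header.get("training_amplitude_deviation")


def build_detector(
    sampling_rate: float, n_filters: int = DEFAULT_N_FILTERS, seed: int = 0
) -> SpikeDetector:
    """Construct an untrained detector for a sampling rate."""
    return SpikeDetector(DetectorConfig(sampling_rate, n_filters), seed=seed)
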