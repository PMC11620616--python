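"""Ground-truth simulator: propagating units, Poisson firing, Gaussian noise.

The simulator reproduces the statistical structure the sorter assumes — not
membrane biophysics.  Each synthetic unit is an axonal propagation: a
biphasic trough-dominant template deposited on a set of electrodes with
fixed sub-millisecond per-electrode latencies (nondecreasing along a
straight propagation path, total ≤ 0.5 ms) and amplitudes that decay
exponentially with distance from the root electrode.  Units fire as
independent Poisson processes (optional refractory floor) with small
per-spike latency and amplitude jitter; white Gaussian noise is added on
top.  The exact spike times, realized latencies and amplitudes are kept as
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .probe import ProbeGeometry, make_probe
from .recording import Recording

__all__ = [
    "SyntheticUnit",
    "GroundTruth",
    "UnitConfig",
    "make_unit",
    "simulate",
    "default_template",
    "make_probe",
]


def default_template(
    sampling_rate: float, duration_ms: float = 3.0
) -> np.ndarray:
    """Biphasic trough-dominant template, trough-centred, trough depth −1.

    A sharp negative deflection (~0.15 ms SD) followed by a slower positive
    overshoot at about a third of the trough depth — the canonical
    extracellular spike shape.
    """
    fpms = sampling_rate / 1000.0
    n = int(round(duration_ms * fpms))
    n += 1 - n % 2  # odd length so the trough sits on the centre frame
    t = (np.arange(n) - n // 2) / fpms  # ms relative to trough
    w = -np.exp(-0.5 * (t / 0.15) ** 2) + 0.35 * np.exp(
        -0.5 * ((t - 0.45) / 0.35) ** 2
    )
    w -= np.linspace(w[0], w[-1], n)  # zero the edges
    return (w / -w.min()).astype(np.float64)


@dataclass
class SyntheticUnit:
    """A simulated neuron: template, per-electrode latency/amplitude, rate."""

    unit_id: int
    template: np.ndarray  # unit amplitude, trough-centred
    electrodes: np.ndarray  # electrode ids carrying signal
    latencies: np.ndarray  # frames (float), 0 at the root
    amplitudes: np.ndarray  # ADC units (positive trough depths)
    rate_hz: float
    latency_jitter_sd: float = 0.5  # frames
    amplitude_jitter_sd: float = 0.08  # fraction

    def __post_init__(self):
        if np.any(self.latencies < 0):
            raise ValueError("latencies must be nonnegative (root = 0)")
        if self.amplitudes.max() <= 0:
            raise ValueError("unit must be detectable on ≥1 electrode")

    @property
    def root_electrode(self) -> int:
        return int(self.electrodes[int(np.argmax(self.amplitudes))])


@dataclass
class GroundTruth:
    """True spike frames per unit plus realized per-spike jitter."""

    units: list[SyntheticUnit]
    spike_frames: dict[int, np.ndarray]  # unit_id -> frames at the root
    realized_latencies: dict[int, np.ndarray] = field(default_factory=dict)
    realized_amplitudes: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class UnitConfig:
    root_electrode: int
    direction_deg: float = 0.0
    path_length_um: float = 100.0
    propagation_ms: float = 0.4  # total root-to-tip latency, ≤ 0.5 ms
    root_amplitude: float = 30.0  # ADC units at the root
    decay_um: float = 40.0  # exponential space constant
    rate_hz: float = 1.0
    detectability_floor: float = 4.0  # drop electrodes below this amplitude
    lateral_um: float = 40.0  # electrodes beyond this distance from the
    # propagation segment carry no signal


def make_unit(
    rng: np.random.Generator,
    geometry: ProbeGeometry,
    config: UnitConfig,
    sampling_rate: float = 20000.0,
    unit_id: int = 0,
) -> SyntheticUnit:
    """Lay a propagation path on the probe and derive per-electrode
    latencies and amplitudes.

    Latencies grow linearly with the projection of each electrode onto the
    path direction (clipped to the path), so they are nonnegative and
    nondecreasing along the propagation; amplitudes decay exponentially
    with distance from the root.
    """
    if config.propagation_ms > 0.5:
        raise ValueError("total propagation must stay within 0.5 ms")
    pos = geometry.positions
    root = pos[config.root_electrode]
    u = np.array(
        [
            np.cos(np.deg2rad(config.direction_deg)),
            np.sin(np.deg2rad(config.direction_deg)),
        ]
    )
    rel = pos - root
    proj = rel @ u
    lateral = np.abs(rel @ np.array([-u[1], u[0]]))
    proj_c = np.clip(proj, 0.0, config.path_length_um)
    seg_dist = np.hypot(proj - proj_c, lateral)  # distance to the segment
    dist_root = np.linalg.norm(rel, axis=1)
    amps = config.root_amplitude * np.exp(-dist_root / config.decay_um)
    mask = (amps >= config.detectability_floor) & (
        seg_dist <= config.lateral_um
    )
    mask[config.root_electrode] = True
    tip = pos[mask]
    if proj_c[mask].max() < 0.6 * config.path_length_um:
        raise ValueError(
            "geometry too small for the requested propagation path"
        )
    del tip
    fpms = sampling_rate / 1000.0
    lat = proj_c[mask] / config.path_length_um * config.propagation_ms * fpms
    return SyntheticUnit(
        unit_id=unit_id,
        template=default_template(sampling_rate),
        electrodes=np.flatnonzero(mask),
        latencies=lat,
        amplitudes=amps[mask],
        rate_hz=config.rate_hz,
    )


def _poisson_train(
    rng: np.random.Generator,
    rate_hz: float,
    n_frames: int,
    sampling_rate: float,
    refractory_ms: float,
) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0, dtype=np.int64)
    refr = refractory_ms / 1000.0
    times = []
    t = 0.0
    horizon = n_frames / sampling_rate
    while True:
        t += rng.exponential(1.0 / rate_hz) + refr
        if t >= horizon:
            break
        times.append(t)
    return (np.asarray(times) * sampling_rate).astype(np.int64)


def simulate(
    units: list[SyntheticUnit],
    duration_s: float,
    noise_sd: float,
    rng: np.random.Generator,
    geometry: ProbeGeometry,
    sampling_rate: float = 20000.0,
    refractory_ms: float = 2.0,
    return_parts: bool = False,
):
    """Render a recording from units + noise; returns (Recording, GroundTruth).

    With ``return_parts=True`` additionally returns the float clean signal
    and the noise realization (before int16 quantization), so the additive
    structure can be audited exactly.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n_frames = int(round(duration_s * sampling_rate))
    n_elec = geometry.n_electrodes
    clean = np.zeros((n_frames, n_elec), dtype=np.float32)
    gt = GroundTruth(units=units, spike_frames={})
    margin = max(
        (u.template.size for u in units), default=0
    ) + int(0.5 * sampling_rate / 1000.0)
    for u in units:
        frames = _poisson_train(
            rng, u.rate_hz, n_frames - 2 * margin, sampling_rate, refractory_ms
        ) + margin
        gt.spike_frames[u.unit_id] = frames
        half = u.template.size // 2
        lat_real = np.empty((frames.size, u.electrodes.size))
        amp_real = np.empty((frames.size, u.electrodes.size))
        for si, f in enumerate(frames):
            jit_l = rng.normal(0.0, u.latency_jitter_sd, u.electrodes.size)
            jit_a = 1.0 + rng.normal(0.0, u.amplitude_jitter_sd, u.electrodes.size)
            for ei, e in enumerate(u.electrodes):
                lat = u.latencies[ei] + jit_l[ei]
                amp = u.amplitudes[ei] * max(jit_a[ei], 0.1)
                centre = int(f + round(lat))
                lo = centre - half
                hi = centre + half + 1
                clean[lo:hi, e] += amp * u.template
                lat_real[si, ei] = centre - f
                amp_real[si, ei] = amp
        gt.realized_latencies[u.unit_id] = lat_real
        gt.realized_amplitudes[u.unit_id] = amp_real
    if noise_sd > 0:
        noise = rng.standard_normal(clean.shape, dtype=np.float32)
        noise *= np.float32(noise_sd)
    else:
        noise = np.zeros_like(clean)
    total = clean + noise
    np.round(total, out=total)
    np.clip(total, -32768, 32767, out=total)
    traces = total.astype(np.int16)
    rec = Recording(traces, sampling_rate, geometry)
    if return_parts:
        return rec, gt, clean, noise
    del total
    return rec, gt
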