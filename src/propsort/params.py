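"""Sorter parameter ledger.

Every tunable of the sorting pipeline lives in one dataclass so a run can be
reproduced from a single record.  Two named profiles ship with the package:
``mea`` (MaxWell-style arrays at 20 kHz) and ``neuropixels`` (30 kHz
checkerboard probes).  The profiles differ where device noise differs:
detection thresholds, the inference scaling numerator, the interval/amplitude
assignment thresholds and the device amplitude cutoffs used when selecting
training waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["Params", "mea_params", "neuropixels_params"]


@dataclass(frozen=True)
class Params:
    # -- detection thresholds (percent of the 0-100 detector score) --------
    stringent_threshold: float  # gates root detections (precision-first)
    loose_threshold: float  # gates supporting detections (recall-first)
    inference_scaling_numerator: float  # training amplitude deviation

    # -- geometry / windows -------------------------------------------------
    propagation_window_ms: float = 0.5  # ± window around a root detection
    amplitude_window_ms: float = 50.0  # amplitude normalization history
    inner_radius_um: float = 50.0
    outer_radius_um: float = 100.0

    # -- noise filters ------------------------------------------------------
    n_elec_noise: int = 100  # min_elec = max(N, M × n_electrodes)
    m_elec_noise: float = 0.10
    n_seq_noise: int = 50  # min_seq = max(N, M × n_electrodes)
    m_seq_noise: float = 0.05
    stringent_codetection_threshold: int = 2  # co-active electrodes incl. root

    # -- interval-cluster splitting ----------------------------------------
    max_gmm_components: int = 4
    n_split: int = 10  # min cluster = max(N, M × codetections)
    m_split: float = 0.10
    expansion_threshold: float = 0.50  # grow splitting-electrode list
    patience: int = 6
    hartigan_p: float = 0.1  # dip-test gate for amplitude splitting

    # -- assignment / merging ----------------------------------------------
    min_median_score: float = 3.0  # median scores below this are zeroed
    min_inner_loose: int = 3
    min_loose: int = 4
    min_loose_fraction: float = 0.33
    max_interval_diff: float = 3.5  # frames (weighted)
    interval_clip: float = 7.0  # frames (= 2 × threshold)
    max_amplitude_diff: float = 65.0  # percent (weighted)
    amplitude_clip: float = 130.0  # percent (= 2 × threshold)
    max_root_amp_z: float = 2.5
    dedup_window_ms: float = 0.2
    use_root_amp_merge_condition: bool = False

    # -- sequence updating / filtering --------------------------------------
    relocation_min_amp_fraction: float = 0.80
    relocation_max_interval: float = -2.0  # frames
    min_spikes: int = 10
    min_rate_hz: float = 0.05

    # -- training-data device cutoffs (physical units of averaged footprints)
    waveform_trough_uv: float = 19.0  # trough must cross −this
    waveform_stability_max: float = 0.6

    def __post_init__(self) -> None:
        if not (0 < self.loose_threshold <= self.stringent_threshold < 100):
            raise ValueError("need 0 < loose ≤ stringent < 100")
        if self.interval_clip < self.max_interval_diff:
            raise ValueError("interval clip below interval threshold")
        if self.amplitude_clip < self.max_amplitude_diff:
            raise ValueError("amplitude clip below amplitude threshold")

    def min_elec_noise(self, n_electrodes: int) -> int:
        return max(self.n_elec_noise, int(self.m_elec_noise * n_electrodes))

    def min_seq_noise(self, n_electrodes: int) -> int:
        return max(self.n_seq_noise, int(self.m_seq_noise * n_electrodes))

    def min_cluster_size(self, n_codetections: int) -> int:
        return max(self.n_split, int(self.m_split * n_codetections))

    def with_overrides(self, **kwargs) -> "Params":
        return replace(self, **kwargs)


def mea_params(**overrides) -> Params:
    """20 kHz MEA profile."""
    return Params(
        stringent_threshold=27.5,
        loose_threshold=10.0,
        inference_scaling_numerator=12.6,
        max_interval_diff=3.5,
        interval_clip=7.0,
        max_amplitude_diff=65.0,
        amplitude_clip=130.0,
        use_root_amp_merge_condition=False,
        waveform_trough_uv=19.0,
    ).with_overrides(**overrides)


def neuropixels_params(**overrides) -> Params:
    """30 kHz Neuropixels profile; denser tissue, stricter assignment."""
    return Params(
        stringent_threshold=17.5,
        loose_threshold=7.5,
        inference_scaling_numerator=15.4,
        max_interval_diff=2.5,
        interval_clip=5.0,
        max_amplitude_diff=45.0,
        amplitude_clip=90.0,
        use_root_amp_merge_condition=True,
        waveform_trough_uv=36.0,
    ).with_overrides(**overrides)
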