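import numpy as np
import pytest

from propsort import ProbeGeometry, Recording, mea_params, neuropixels_params
from propsort.simulate import default_template
from propsort.training_data import (
    DetectorSource,
    SortedUnit,
    WaveformBank,
    WaveformBankEntry,
    build_epoch,
    curate_units,
    electrode_passes_selection,
    extract_noise_snippets,
    synthesize_sample,
)

RATE = 20000.0
PARAMS = mea_params()


def _recording(n_frames=40000, n_elec=2, seed=0):
    rng = np.random.default_rng(seed)
    geom = ProbeGeometry(
        np.column_stack([np.arange(n_elec) * 35.0, np.zeros(n_elec)])
    )
    return Recording(
        rng.integers(-5, 5, (n_frames, n_elec)).astype(np.int16), RATE, geom
    )


def _unit(uid, frames, main=0):
    return SortedUnit(uid, np.asarray(frames, dtype=np.int64), main)


def _spiky_recording(frames, amp=-60, n_frames=60000):
    rec = _recording(n_frames)
    tpl = (default_template(RATE) * -amp * -1).astype(np.int16)
    half = tpl.size // 2
    traces = rec.traces.copy()
    for f in frames:
        traces[f - half : f + half + 1, 0] += tpl
    return Recording(traces, RATE, rec.geometry)


class TestCuration:
    def test_spike_count_thresholds(self):
        spacing = 400
        mk = lambda n: list(range(2000, 2000 + n * spacing, spacing))
        rec = _spiky_recording(mk(100))
        u29 = _unit(0, mk(29))
        u40 = _unit(1, mk(40))
        u60 = _unit(2, mk(60))
        r1, r2 = curate_units([u29, u40, u60], rec)
        ids1 = {u.unit_id for u in r1}
        ids2 = {u.unit_id for u in r2}
        assert ids1 == {1, 2}  # 29 spikes fails round 1
        assert ids2 == {2}  # 40 spikes passes round 1 but not round 2

    def test_isi_violations_exclude_unit(self):
        base = list(range(2000, 2000 + 100 * 400, 400))
        # add two violating spikes (2 % > 1 % at 1.5 ms)
        bad = sorted(base + [base[10] + 10, base[20] + 10])
        rec = _spiky_recording(base)
        r1, _ = curate_units([_unit(0, bad)], rec)
        assert r1 == []

    def test_low_snr_excluded(self):
        frames = list(range(2000, 2000 + 60 * 400, 400))
        rec = _recording()  # no spikes deposited → SNR ≈ 0
        r1, _ = curate_units([_unit(0, frames)], rec)
        assert r1 == []


class TestElectrodeSelection:
    def test_trough_rule(self):
        w = np.zeros(100)
        w[50] = -20.0
        amps = np.full(30, -20.0)
        assert electrode_passes_selection(w, amps, PARAMS)

    def test_shallow_trough_rejected(self):
        w = np.zeros(100)
        w[50] = -10.0
        assert not electrode_passes_selection(w, np.full(30, -10.0), PARAMS)

    def test_peak_rule_admits_positive_spikes(self):
        w = np.zeros(100)
        w[50] = 25.0
        w[60] = -10.0  # peak 2.5× the trough and above +19 μV
        assert electrode_passes_selection(w, np.full(30, 25.0), PARAMS)

    def test_unstable_amplitudes_rejected(self):
        w = np.zeros(100)
        w[50] = -30.0
        rng = np.random.default_rng(0)
        amps = rng.normal(-30, 21.5, 500)  # stability ratio ≈ 0.7
        assert not electrode_passes_selection(w, amps, PARAMS)

    def test_neuropixels_cutoff_is_stricter(self):
        w = np.zeros(100)
        w[50] = -25.0
        amps = np.full(30, -25.0)
        assert electrode_passes_selection(w, amps, PARAMS)
        assert not electrode_passes_selection(w, amps, neuropixels_params())


class TestNoiseSnippets:
    def test_guard_band_excludes_nearby_spikes(self):
        rec = _recording(n_frames=4000)
        win = 200
        # trough 2 ms before the second window start → rejected
        troughs = np.array([win - 40])
        snips = extract_noise_snippets(rec, troughs)
        n_windows = snips.shape[1]
        all_windows = rec.n_frames // win
        assert n_windows == all_windows - 2  # windows 0 and 1 both tainted

    def test_guard_band_boundary_4ms_is_clean(self):
        rec = _recording(n_frames=4000)
        # trough 4 ms (80 frames) before window 1 → only window 0 tainted
        snips = extract_noise_snippets(rec, np.array([200 - 80]))
        assert snips.shape[1] == rec.n_frames // 200 - 1

    def test_spike_free_recording_keeps_every_window(self):
        rec = _recording(n_frames=4000)
        snips = extract_noise_snippets(rec, np.empty(0, np.int64))
        assert snips.shape == (2, 20, 200)


def _bank(n=6):
    tpl = default_template(RATE)
    bank = WaveformBank()
    for i in range(n):
        w = (tpl * (20 + 3 * i)).astype(np.float32)
        bank.entries.append(
            WaveformBankEntry(i, i, w, int(tpl.argmin()), float(w.min()),
                              float(w.max()), 0.3)
        )
    return bank


class TestSynthesis:
    def test_deterministic_under_seed(self):
        bank = _bank()
        noise = np.zeros(200, np.float32)
        a = synthesize_sample(noise, bank, np.random.default_rng(42), RATE)
        b = synthesize_sample(noise, bank, np.random.default_rng(42), RATE)
        assert np.array_equal(a.trace, b.trace)
        assert a.gt_troughs == b.gt_troughs and a.sources == b.sources

    def test_additivity_of_pasted_waveforms(self):
        bank = _bank()
        rng = np.random.default_rng(7)
        noise = rng.normal(0, 3, 200).astype(np.float32)
        for _ in range(50):
            s = synthesize_sample(noise, bank, rng, RATE)
            resid = s.trace - noise
            expected = np.zeros(200, np.float32)
            for t, k in zip(s.gt_troughs, s.sources):
                e = bank.entries[k]
                start = t - e.trough_index
                lo, hi = max(0, start), min(200, start + e.waveform.size)
                expected[lo:hi] += e.waveform[lo - start : hi - start]
            assert np.allclose(resid, expected, atol=1e-5)

    def test_troughs_inside_scored_span_and_spacing_bounds(self):
        bank = _bank()
        rng = np.random.default_rng(8)
        noise = np.zeros(200, np.float32)
        for _ in range(2000):
            s = synthesize_sample(noise, bank, rng, RATE)
            for t in s.gt_troughs:
                assert 40 <= t < 160
            ts = np.sort(s.gt_troughs)
            if ts.size >= 2:
                d = np.diff(ts)
                assert d.min() >= 4  # 0.2 ms at 20 kHz
                assert ts[-1] - ts[0] <= 120  # 6 ms
            assert len(set(s.sources)) == len(s.sources)

    def test_count_distribution_chi_square(self):
        from scipy.stats import chisquare

        bank = _bank()
        rng = np.random.default_rng(9)
        noise = np.zeros(200, np.float32)
        counts = np.zeros(5, int)
        n = 20000
        for _ in range(n):
            s = synthesize_sample(noise, bank, rng, RATE)
            counts[len(s.gt_troughs)] += 1
        expected = np.array([0.50, 0.30, 0.12, 0.06, 0.02]) * n
        assert chisquare(counts, expected).pvalue > 0.01

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            synthesize_sample(
                np.zeros(200, np.float32), WaveformBank(), np.random.default_rng(0), RATE
            )


class TestBuildEpoch:
    def _sources(self, n=3):
        rng = np.random.default_rng(0)
        out = []
        for i in range(n):
            noise = rng.normal(0, 3, (2, 10, 200)).astype(np.float32)
            out.append(
                DetectorSource(name=f"s{i}", bank=_bank(4), noise_snippets=noise)
            )
        return out

    def test_sample_counts_per_waveform(self):
        sources = self._sources()
        train, val = build_epoch(sources, 2, RATE, 20, 2, np.random.default_rng(1))
        assert len(train) == 20 * 8  # two training banks of 4 waveforms
        assert len(val) == 2 * 4

    def test_neuropixels_style_single_sample_per_waveform(self):
        sources = self._sources()
        train, val = build_epoch(sources, 0, RATE, 1, 1, np.random.default_rng(2))
        assert len(train) == 8 and len(val) == 4

    def test_fold_leakage_rejected(self):
        sources = self._sources()
        sources[0].name = sources[1].name = "dup"
        with pytest.raises(ValueError):
            build_epoch(sources, 0, RATE, 1, 1, np.random.default_rng(3))
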