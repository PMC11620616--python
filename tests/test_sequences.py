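import numpy as np
import pytest

from propsort import ProbeGeometry, Recording, mea_params
from propsort.detector.infer import DetectionScores
from propsort.sequences import (
    PreliminarySequence,
    PropagationSequence,
    amplitude_split,
    build_context,
    codetection_intervals,
    extract_metrics,
    find_root_detections,
    grow_sequences,
    split_intervals,
)

RATE = 20000.0


def _line_geom(n, pitch=35.0):
    return ProbeGeometry(np.column_stack([np.arange(n) * pitch, np.zeros(n)]))


def _ctx(n_elec, n_frames, spikes, params=None, geom=None):
    """Construct a context from (electrode, frame, score, amplitude) spikes.

    Each spike writes a score peak and a raw trough of the requested
    standardized amplitude (traces are zero elsewhere, so the standardized
    amplitude is −2 × the raw trough depth via the 0.5 noise floor).
    """
    params = params or mea_params()
    geom = geom or _line_geom(n_elec)
    traces = np.zeros((n_frames, n_elec), dtype=np.int16)
    scores = np.zeros((n_frames, n_elec), dtype=np.float32)
    for e, f, sc, amp in spikes:
        scores[f, e] = sc
        traces[f, e] = int(round(-amp / 2.0))
    rec = Recording(traces, RATE, geom)
    ds = DetectionScores(scores, 40, n_frames - 40, RATE)
    return build_context(rec, ds, params)


class TestCodetectionIntervals:
    def test_signed_interval_in_frames(self):
        idx, iv = codetection_intervals(
            np.array([1000]), np.array([1004]), 10
        )
        assert idx.tolist() == [0] and iv.tolist() == [4.0]

    def test_outside_half_ms_window_is_no_codetection(self):
        idx, iv = codetection_intervals(np.array([1000]), np.array([1012]), 10)
        assert idx.size == 0

    def test_nearest_candidate_wins(self):
        idx, iv = codetection_intervals(
            np.array([1000]), np.array([991, 1002]), 10
        )
        assert iv.tolist() == [2.0]

    def test_one_to_one_consumption(self):
        # two roots, one splitting detection: only the nearer root matches
        idx, iv = codetection_intervals(
            np.array([1000, 1006]), np.array([1005]), 10
        )
        assert idx.tolist() == [1] and iv.tolist() == [-1.0]


class TestSplitIntervals:
    def test_unimodal_sample_stays_together(self):
        rng = np.random.default_rng(0)
        iv = rng.normal(3.0, 0.3, 100)
        clusters = split_intervals(iv, mea_params())
        assert len(clusters) == 1
        assert clusters[0].size == 100

    def test_bimodal_sample_partitioned_at_boundary(self):
        rng = np.random.default_rng(1)
        iv = np.concatenate([rng.normal(2, 0.3, 60), rng.normal(8, 0.3, 60)])
        clusters = split_intervals(iv, mea_params())
        assert len(clusters) == 2
        got = {frozenset(c.tolist()) for c in clusters}
        want = {frozenset(range(60)), frozenset(range(60, 120))}
        assert got == want

    def test_minority_cluster_below_size_rule_discarded(self):
        rng = np.random.default_rng(2)
        iv = np.concatenate([rng.normal(2, 0.3, 95), rng.normal(8, 0.3, 5)])
        clusters = split_intervals(iv, mea_params())
        # the 5-member mode fails max(10, 10 % of 100) and is dropped
        assert len(clusters) == 1
        assert clusters[0].size == 95
        assert np.all(iv[clusters[0]] < 5)

    def test_agrees_with_threshold_oracle_on_separated_modes(self):
        # ≥5σ separation: a mid-point threshold split is unambiguous and
        # the mixture partition must reproduce it exactly
        params = mea_params()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(1.0, 0.4, 50)
            b = rng.normal(7.0, 0.4, 70)
            iv = np.concatenate([a, b])
            clusters = split_intervals(iv, params, seed=0)
            oracle = {
                frozenset(np.flatnonzero(iv < 4.0).tolist()),
                frozenset(np.flatnonzero(iv >= 4.0).tolist()),
            }
            assert {frozenset(c.tolist()) for c in clusters} == oracle

    def test_empty_sample(self):
        assert split_intervals(np.empty(0), mea_params()) == []


def _root_spikes(root_times, lat_by_elec, score=60.0, amp_by_elec=None):
    spikes = []
    for t in root_times:
        for e, lat in lat_by_elec.items():
            amp = (amp_by_elec or {}).get(e, 20.0)
            spikes.append((e, int(t + lat), score, amp))
    return spikes


class TestFindRootDetections:
    def test_max_amplitude_electrode_collects_root_detections(self):
        times = np.arange(2000, 50000, 400)
        spikes = _root_spikes(
            times, {0: 0, 1: 0, 2: 1}, amp_by_elec={0: 10, 1: 30, 2: 15}
        )
        ctx = _ctx(4, 60000, spikes)
        roots = find_root_detections(ctx)
        assert 1 in roots
        assert roots[1].size == times.size
        assert 0 not in roots  # dominated by electrode 1 within 100 μm

    def test_larger_amplitude_on_outer_electrode_disqualifies(self):
        times = np.arange(2000, 50000, 400)
        spikes = []
        for t in times:
            spikes.append((1, t, 60.0, 20.0))
            spikes.append((0, t + 1, 60.0, 25.0))  # bigger, 0.05 ms later
            spikes.append((2, t + 1, 60.0, 5.0))
        ctx = _ctx(3, 60000, spikes)
        roots = find_root_detections(ctx)
        assert 1 not in roots

    def test_requires_inner_codetection_within_01ms(self):
        times = np.arange(2000, 50000, 400)
        # codetection 0.25 ms away: inside the 0.5 ms amplitude window but
        # outside the 0.1 ms codetection window
        spikes = _root_spikes(times, {1: 0, 0: 5}, amp_by_elec={1: 30, 0: 5})
        ctx = _ctx(3, 60000, spikes)
        assert 1 not in find_root_detections(ctx)

    def test_low_rate_electrodes_dropped(self):
        times = np.array([2000, 3000])  # 2 detections in 50 s = 0.04 Hz
        spikes = _root_spikes(times, {1: 0, 0: 1}, amp_by_elec={1: 30, 0: 10})
        ctx = _ctx(3, 1000000, spikes)
        assert 1 not in find_root_detections(ctx)

    def test_simultaneous_array_wide_events_removed_as_noise(self):
        params = mea_params(n_elec_noise=3)
        times = np.arange(2000, 50000, 400)
        spikes = []
        for t in times:
            for e in range(4):  # all 4 ≥ max(3, 0.4) electrodes same frame
                spikes.append((e, t, 60.0, 20.0))
        ctx = _ctx(4, 60000, spikes, params=params)
        assert find_root_detections(ctx) == {}


class TestGrowSequences:
    def test_single_unit_grows_one_sequence(self):
        times = np.arange(2000, 50000, 400)
        spikes = _root_spikes(
            times, {0: 2, 1: 0, 2: 1}, amp_by_elec={1: 30, 0: 10, 2: 15}
        )
        ctx = _ctx(4, 60000, spikes)
        roots = find_root_detections(ctx)
        seqs = grow_sequences(ctx, roots)
        mine = [s for s in seqs if s.root_electrode == 1]
        assert len(mine) == 1
        assert mine[0].member_times.size == times.size

    def test_two_neurons_sharing_root_are_separated(self):
        # both neurons co-detect simultaneously on electrode 0 (which
        # qualifies their root detections) but propagate to electrode 2
        # with distinct latencies: the interval mixture on electrode 2
        # must pull them apart
        rng = np.random.default_rng(0)
        a_times = np.arange(2000, 50000, 800)
        b_times = a_times + 397  # interleaved

        def jittered(times, lat2):
            out = []
            for t in times:
                j = int(rng.integers(-1, 2))
                out += _root_spikes(
                    [t], {1: 0, 0: 0, 2: lat2 + j},
                    amp_by_elec={1: 30, 0: 8, 2: 12},
                )
            return out

        spikes = jittered(a_times, 3) + jittered(b_times, 9)
        ctx = _ctx(4, 60000, spikes)
        roots = find_root_detections(ctx)
        assert roots[1].size == 120
        seqs = [s for s in grow_sequences(ctx, roots) if s.root_electrode == 1]
        assert len(seqs) == 2
        sets = sorted(
            (np.sort(s.member_times) for s in seqs), key=lambda x: x[0]
        )
        assert np.array_equal(sets[0], a_times)
        assert np.array_equal(sets[1], b_times)

    def test_isolated_root_without_codetections_yields_nothing(self):
        times = np.arange(2000, 50000, 400)
        spikes = [(1, int(t), 60.0, 30.0) for t in times]
        # inner codetection within 0.1 ms exists but carries no recurring
        # propagation beyond it
        ctx = _ctx(3, 60000, spikes)
        roots = find_root_detections(ctx)
        assert roots == {}  # no inner codetection at all → no roots

    def test_partition_property_no_detection_in_two_sequences(self, grid):
        a_times = np.arange(2000, 50000, 800)
        b_times = a_times + 397
        spikes = _root_spikes(a_times, {1: 0, 0: 2, 2: 1}, amp_by_elec={1: 30, 0: 12, 2: 12})
        spikes += _root_spikes(b_times, {1: 0, 0: 9, 2: 8}, amp_by_elec={1: 30, 0: 12, 2: 12})
        ctx = _ctx(4, 60000, spikes)
        seqs = grow_sequences(ctx, find_root_detections(ctx))
        by_root: dict[int, list] = {}
        for s in seqs:
            by_root.setdefault(s.root_electrode, []).append(s)
        for root, ss in by_root.items():
            allt = np.concatenate([s.member_times for s in ss])
            assert np.unique(allt).size == allt.size


class TestSerialization:
    def test_sequence_roundtrip_through_json(self):
        import json

        from propsort.sequences import sequence_from_dict, sequence_to_dict

        seq = PropagationSequence(
            sequence_id=3,
            root_electrode=1,
            member_times=np.array([100, 200, 300]),
            splitting_electrodes=[1, 0],
            loose=np.array([0, 1, 2, 3]),
            inner_loose=np.array([0, 1, 2]),
            footprint=np.array([0, 1, 2, 3, 4]),
            median_score=np.array([50.0, 60.0, 40.0, 20.0, 0.0]),
            mean_interval=np.array([1.0, 0.0, 2.0, 3.0, np.nan]),
            mean_amplitude=np.array([-10.0, -20.0, -8.0, -5.0, np.nan]),
            root_amplitude_sd=1.5,
            member_root_amplitudes=np.array([-19.0, -21.0, -20.0]),
        )
        doc = json.loads(json.dumps(sequence_to_dict(seq)))
        again = sequence_from_dict(doc)
        assert again.sequence_id == 3 and again.root_electrode == 1
        assert np.array_equal(again.member_times, seq.member_times)
        assert np.array_equal(again.footprint, seq.footprint)
        assert np.allclose(again.mean_interval, seq.mean_interval, equal_nan=True)
        assert again.root_amplitude_sd == seq.root_amplitude_sd


class TestAmplitudeSplit:
    def _seq_ctx(self, amps_per_spike):
        """Plant root troughs of the given depths on a noisy background so
        standardized amplitudes are effectively continuous (as on a real
        device, where the robust noise scale varies window to window)."""
        times = np.arange(2000, 2000 + 400 * len(amps_per_spike), 400)
        n_frames = int(times[-1] + 2000)
        rng = np.random.default_rng(77)
        geom = _line_geom(3)
        traces = rng.normal(0, 3, (n_frames, 3)).round().astype(np.int16)
        scores = np.zeros((n_frames, 3), dtype=np.float32)
        for t, amp in zip(times, amps_per_spike):
            scores[int(t), 1] = 60.0
            traces[int(t), 1] = int(round(-amp))
            scores[int(t) + 2, 0] = 60.0
            traces[int(t) + 2, 0] = int(round(-amp / 2))
        from propsort import Recording
        from propsort.detector.infer import DetectionScores

        rec = Recording(traces, RATE, geom)
        ctx = build_context(rec, DetectionScores(scores, 40, n_frames - 40, RATE), mea_params())
        seq = PreliminarySequence(1, times, [1, 0])
        return ctx, seq

    def test_unimodal_amplitudes_stay_together(self):
        # amplitudes well above the int16 quantization step, one Gaussian
        rng = np.random.default_rng(0)
        ctx, seq = self._seq_ctx(rng.normal(160, 12, 60))
        out = amplitude_split(ctx, seq)
        assert len(out) == 1
        assert np.array_equal(out[0].member_times, seq.member_times)

    def test_bimodal_amplitudes_split_in_two(self):
        # the S12-style scenario: two same-interval neurons whose root
        # amplitudes sit at −x and −2x standardized units
        rng = np.random.default_rng(1)
        amps = np.concatenate([rng.normal(64, 3.2, 50), rng.normal(128, 3.2, 50)])
        ctx, seq = self._seq_ctx(amps)
        out = amplitude_split(ctx, seq)
        assert len(out) == 2
        sizes = sorted(o.member_times.size for o in out)
        assert sizes == [50, 50]

    def test_minority_branch_below_min_spikes_discarded(self):
        rng = np.random.default_rng(2)
        amps = np.concatenate([rng.normal(64, 2.4, 95), rng.normal(160, 2.4, 5)])
        ctx, seq = self._seq_ctx(amps)
        out = amplitude_split(ctx, seq)
        assert all(o.member_times.size >= 10 for o in out)


class TestExtractMetrics:
    GEOM_2X3 = ProbeGeometry(
        np.array([[0, 0], [35, 0], [70, 0], [0, 35], [35, 35], [70, 35]], float)
    )
    LAT = {0: 0, 1: 1, 2: 2, 3: 1, 4: 2, 5: 3}

    def _propagation_ctx(self, n_members=50, score_on_tail=60.0):
        amp = {0: 240, 1: 200, 2: 150, 3: 190, 4: 140, 5: 100}
        times = np.arange(2000, 2000 + 400 * n_members, 400)
        spikes = []
        for t in times:
            for e, l in self.LAT.items():
                sc = 60.0 if e < 5 else score_on_tail
                spikes.append((e, int(t + l), sc, amp[e]))
        ctx = _ctx(
            6, int(times[-1]) + 2000, spikes, geom=self.GEOM_2X3
        )
        return ctx, PreliminarySequence(0, times, [0, 1, 2, 3, 4, 5])

    def test_mean_intervals_recover_true_latencies(self):
        ctx, seq = self._propagation_ctx()
        m = extract_metrics(ctx, seq)
        assert m is not None
        for e, true_lat in self.LAT.items():
            assert m.mean_interval[e] == pytest.approx(true_lat, abs=0.5)
        assert m.root_electrode == 0
        assert set(m.loose.tolist()) == {0, 1, 2, 3, 4, 5}
        assert set(m.inner_loose.tolist()) == {0, 1, 3, 4}

    def test_low_median_scores_are_zeroed(self):
        ctx, seq = self._propagation_ctx(score_on_tail=2.9)
        m = extract_metrics(ctx, seq)
        assert m is not None
        assert m.median_score[5] == 0.0

    def test_too_few_loose_electrodes_discards_sequence(self):
        # only 3 electrodes carry detections → fewer than 4 loose
        times = np.arange(2000, 2000 + 400 * 50, 400)
        spikes = []
        for t in times:
            for e in (0, 1, 3):
                spikes.append((e, int(t + self.LAT[e]), 60.0, 200.0))
        ctx = _ctx(6, int(times[-1]) + 2000, spikes, geom=self.GEOM_2X3)
        assert extract_metrics(ctx, PreliminarySequence(0, times, [0, 1, 3])) is None

    def test_raising_loose_threshold_never_grows_loose_set(self):
        ctx, seq = self._propagation_ctx()
        base = extract_metrics(ctx, seq)
        stricter = mea_params(loose_threshold=25.0, stringent_threshold=27.5)
        ctx2 = build_context(ctx.recording, ctx.scores, stricter)
        out = extract_metrics(ctx2, seq)
        if out is not None:
            assert set(out.loose.tolist()) <= set(base.loose.tolist())
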