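"""Spike assignment, duplicate resolution and sequence merging.

A spike is assigned to a sequence only when the full propagation pattern
recurs: a stringent detection on the root electrode with a plausible
amplitude (z ≤ 2.5 against the sequence's root-amplitude distribution),
enough loose/inner-loose electrodes co-detecting within the ±0.5 ms
propagation period, and weighted interelectrode-interval and amplitude
differences below the device thresholds.  Electrode weights are the
sequence's median detection scores normalized over the footprint;
differences are clipped at twice the thresholds so a single outlying
electrode cannot dominate.

When several sequences claim the same spike (same root electrode, or roots
within 0.2 ms that are inner electrodes of each other), a difference score
— interval term + amplitude term − 0.5 × (fraction of loose electrodes
detecting) — keeps only the best-matching sequence.

Over-split sequences are merged in two greedy rounds (same root electrode,
then mutually-inner root electrodes), lowest merge score first, with
metrics recomputed from the pooled member spikes after every merge, and a
root-relocation step between rounds that moves the root to an earlier,
comparable-amplitude electrode on the propagation path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import Params
from .sequences import (
    PreliminarySequence,
    PropagationSequence,
    SortingContext,
    extract_metrics,
    _window_peak,
    _amplitudes_at,
)

__all__ = [
    "SpikeFeatures",
    "weighted_difference",
    "spike_features",
    "sequence_spike_table",
    "assign_spike",
    "resolve_duplicates",
    "merge_eligible",
    "merge_all",
    "relocate_root",
    "reassign_all",
]


# ---------------------------------------------------------------- differences
def weighted_difference(
    spike_values: np.ndarray,
    sequence_means: np.ndarray,
    weights: np.ndarray,
    kind: str,
    params: Params,
) -> float:
    """Score-weighted difference between a spike and a sequence.

    ``kind='interval'``: per-electrode |Δ| in frames, clipped at the
    interval clip.  ``kind='amplitude'``: per-electrode percent difference
    relative to the sequence mean, clipped at the amplitude clip.  Weights
    are normalized over the provided electrodes; zero-weight electrodes
    contribute nothing.
    """
    w = np.asarray(weights, dtype=np.float64)
    total = w.sum()
    if total <= 0:
        raise ValueError("all electrode weights are zero")
    w = w / total
    sv = np.asarray(spike_values, dtype=np.float64)
    sm = np.asarray(sequence_means, dtype=np.float64)
    if kind == "interval":
        d = np.abs(sv - sm)
        d = np.minimum(d, params.interval_clip)
    elif kind == "amplitude":
        denom = np.abs(sm)
        safe = denom > 1e-9
        d = np.zeros_like(sv)
        d[safe] = 100.0 * np.abs(sv[safe] - sm[safe]) / denom[safe]
        d = np.minimum(d, params.amplitude_clip)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    valid = np.isfinite(d)
    d = np.where(valid, d, 0.0)
    w = np.where(valid, w, 0.0)
    if w.sum() <= 0:
        raise ValueError("no finite electrode differences")
    return float((d * w).sum() / w.sum())


@dataclass
class SpikeFeatures:
    """A candidate spike measured against one sequence's footprint."""

    time: int
    root_amplitude: float
    intervals: np.ndarray  # per footprint electrode, frames
    amplitudes: np.ndarray  # per footprint electrode, standardized
    n_loose_detecting: int
    n_inner_loose_detecting: int
    n_loose_crossing: int  # footprint electrodes with any loose crossing


def spike_features(
    ctx: SortingContext, seq: PropagationSequence, time: int
) -> SpikeFeatures:
    """Measure one stringent root detection against a sequence."""
    p = ctx.params
    w = ctx.frames(p.propagation_window_ms)
    t = np.asarray([time], dtype=np.int64)
    peak, frames = _window_peak(ctx, t, seq.footprint, w)
    peak = peak[0]
    frames = frames[0]
    root_col = int(np.flatnonzero(seq.footprint == seq.root_electrode)[0])
    intervals = (frames - frames[root_col]).astype(np.float64)
    amps = np.empty(seq.footprint.size)
    for c, e in enumerate(seq.footprint):
        amps[c] = _amplitudes_at(ctx, int(e), frames[c : c + 1])[0]
    detecting = peak > p.loose_threshold
    loose_set = set(int(e) for e in seq.loose)
    inner_set = set(int(e) for e in seq.inner_loose)
    n_loose = sum(
        1 for c, e in enumerate(seq.footprint) if detecting[c] and int(e) in loose_set
    )
    n_inner = sum(
        1 for c, e in enumerate(seq.footprint) if detecting[c] and int(e) in inner_set
    )
    return SpikeFeatures(
        time=int(time),
        root_amplitude=float(amps[root_col]),
        intervals=intervals,
        amplitudes=amps,
        n_loose_detecting=n_loose,
        n_inner_loose_detecting=n_inner,
        n_loose_crossing=int(detecting.sum()),
    )


def sequence_spike_table(
    ctx: SortingContext, seq: PropagationSequence, times: np.ndarray
) -> dict[str, np.ndarray]:
    """Bulk :func:`spike_features` for many candidate times of one sequence.

    Returns arrays keyed ``root_amplitude`` (n,), ``intervals`` /
    ``amplitudes`` (n, n_footprint), and the loose-detection counts.
    """
    p = ctx.params
    w = ctx.frames(p.propagation_window_ms)
    times = np.asarray(times, dtype=np.int64)
    peak, frames = _window_peak(ctx, times, seq.footprint, w)
    root_col = int(np.flatnonzero(seq.footprint == seq.root_electrode)[0])
    intervals = (frames - frames[:, root_col : root_col + 1]).astype(np.float64)
    amps = np.empty(frames.shape, dtype=np.float64)
    for c, e in enumerate(seq.footprint):
        amps[:, c] = _amplitudes_at(ctx, int(e), frames[:, c])
    detecting = peak > p.loose_threshold
    loose_cols = np.isin(seq.footprint, seq.loose)
    inner_cols = np.isin(seq.footprint, seq.inner_loose)
    return {
        "times": times,
        "root_amplitude": amps[:, root_col],
        "intervals": intervals,
        "amplitudes": amps,
        "n_loose_detecting": detecting[:, loose_cols].sum(axis=1),
        "n_inner_loose_detecting": detecting[:, inner_cols].sum(axis=1),
        "n_loose_crossing": detecting.sum(axis=1),
    }


def _bulk_weighted(diffs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted mean with NaN masking; NaN rows yield inf."""
    valid = np.isfinite(diffs)
    w = np.where(valid, weights[None, :], 0.0)
    total = w.sum(axis=1)
    num = np.where(valid, diffs, 0.0)
    out = np.full(diffs.shape[0], np.inf)
    ok = total > 0
    out[ok] = (num * w).sum(axis=1)[ok] / total[ok]
    return out


def _bulk_scores(
    ctx: SortingContext, seq: PropagationSequence, table: dict
) -> tuple[np.ndarray, np.ndarray]:
    """(assignable mask, difference scores) for a sequence's spike table."""
    p = ctx.params
    sd = max(seq.root_amplitude_sd, 1e-9)
    mean_root = seq.mean_amplitude[seq.root_electrode]
    z_ok = (
        np.abs(table["root_amplitude"] - mean_root) / sd <= p.max_root_amp_z
    )
    need_loose = max(
        p.min_loose, math.ceil(p.min_loose_fraction * seq.loose.size)
    )
    count_ok = (table["n_inner_loose_detecting"] >= p.min_inner_loose) & (
        table["n_loose_detecting"] >= need_loose
    )
    weights = seq.median_score[seq.footprint]
    total_w = weights.sum()
    if total_w <= 0:
        n = table["times"].size
        return np.zeros(n, bool), np.full(n, np.inf)
    wn = weights / total_w
    di = _bulk_weighted(
        np.minimum(
            np.abs(table["intervals"] - seq.mean_interval[seq.footprint][None, :]),
            p.interval_clip,
        ),
        wn,
    )
    means_a = seq.mean_amplitude[seq.footprint][None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = 100.0 * np.abs(table["amplitudes"] - means_a) / np.abs(means_a)
    da = _bulk_weighted(np.minimum(pa, p.amplitude_clip), wn)
    ok = (
        z_ok
        & count_ok
        & (di <= p.max_interval_diff)
        & (da <= p.max_amplitude_diff)
    )
    bonus = np.zeros(di.shape)
    crossing = table["n_loose_crossing"]
    nz = crossing > 0
    bonus[nz] = -0.5 * table["n_loose_detecting"][nz] / crossing[nz]
    score = di / p.max_interval_diff + da / p.max_amplitude_diff + bonus
    return ok, score


def assign_spike(
    ctx: SortingContext,
    seq: PropagationSequence,
    feat: SpikeFeatures,
) -> bool:
    """All four assignment conditions for one spike against one sequence."""
    p = ctx.params
    sd = max(seq.root_amplitude_sd, 1e-9)
    mean_root = seq.mean_amplitude[seq.root_electrode]
    if abs(feat.root_amplitude - mean_root) / sd > p.max_root_amp_z:
        return False
    need_loose = max(p.min_loose, math.ceil(p.min_loose_fraction * seq.loose.size))
    if feat.n_inner_loose_detecting < p.min_inner_loose:
        return False
    if feat.n_loose_detecting < need_loose:
        return False
    weights = seq.median_score[seq.footprint]
    means_i = seq.mean_interval[seq.footprint]
    means_a = seq.mean_amplitude[seq.footprint]
    try:
        di = weighted_difference(feat.intervals, means_i, weights, "interval", p)
        da = weighted_difference(feat.amplitudes, means_a, weights, "amplitude", p)
    except ValueError:
        return False
    return di <= p.max_interval_diff and da <= p.max_amplitude_diff


def _difference_score(
    ctx: SortingContext, seq: PropagationSequence, feat: SpikeFeatures
) -> float:
    p = ctx.params
    weights = seq.median_score[seq.footprint]
    di = weighted_difference(
        feat.intervals, seq.mean_interval[seq.footprint], weights, "interval", p
    )
    da = weighted_difference(
        feat.amplitudes, seq.mean_amplitude[seq.footprint], weights, "amplitude", p
    )
    bonus = 0.0
    if feat.n_loose_crossing > 0:
        bonus = -0.5 * feat.n_loose_detecting / feat.n_loose_crossing
    return di / p.max_interval_diff + da / p.max_amplitude_diff + bonus


def resolve_duplicates(
    entries: list[dict],
    params: Params,
    frames_dedup: int,
    geometry,
    mutually_inner: bool,
) -> list[dict]:
    """Keep one candidate per duplicate group.

    Each entry is ``{"sequence_id", "root", "time", "score"}``.  Greedy
    non-maximum suppression: candidates are accepted in ascending
    difference score (ties → lower sequence id, earlier time); a candidate
    conflicts with an accepted one when their times differ by at most the
    0.2 ms dedup window and their root electrodes are identical or
    (``mutually_inner``) within the inner radius of each other.  With
    distinct scores the outcome is independent of input order.
    """
    order = sorted(
        entries, key=lambda c: (c["score"], c["sequence_id"], c["time"])
    )
    accepted: list[dict] = []
    for c in order:
        ok = True
        for a in accepted:
            if abs(c["time"] - a["time"]) > frames_dedup:
                continue
            same_root = c["root"] == a["root"]
            near = (
                mutually_inner
                and geometry.distance(c["root"], a["root"])
                <= params.inner_radius_um
            )
            if same_root or near:
                ok = False
                break
        if ok:
            accepted.append(c)
    accepted.sort(key=lambda c: (c["time"], c["sequence_id"]))
    return accepted


# -------------------------------------------------------------------- merging
def _pair_weights(a: PropagationSequence, b: PropagationSequence):
    common = np.intersect1d(a.footprint, b.footprint)
    w = a.median_score[common] + b.median_score[common]
    return common, w


def merge_eligible(
    a: PropagationSequence,
    b: PropagationSequence,
    params: Params,
    reference_root: int | None = None,
) -> tuple[bool, float]:
    """Check merge conditions for a sequence pair; returns (ok, score).

    ``reference_root`` re-references both interval vectors (round 2, where
    the pair's roots differ); round 1 passes None and uses the shared root.
    The root electrode is excluded from the interval term.  The amplitude
    term uses midpoint percent differences.  The optional root-amplitude
    z condition guards against merging distinct-amplitude units.
    """
    inner_overlap = np.intersect1d(a.inner_loose, b.inner_loose).size
    if inner_overlap < params.min_inner_loose:
        return False, np.inf
    loose_union = np.union1d(a.loose, b.loose).size
    loose_overlap = np.intersect1d(a.loose, b.loose).size
    need = max(params.min_loose, math.ceil(params.min_loose_fraction * loose_union))
    if loose_overlap < need:
        return False, np.inf
    common, w = _pair_weights(a, b)
    if common.size == 0 or w.sum() <= 0:
        return False, np.inf
    ia = a.mean_interval[common].copy()
    ib = b.mean_interval[common].copy()
    if reference_root is not None:
        if not (
            np.isfinite(a.mean_interval[reference_root])
            and np.isfinite(b.mean_interval[reference_root])
        ):
            return False, np.inf
        ia -= a.mean_interval[reference_root]
        ib -= b.mean_interval[reference_root]
        roots = {a.root_electrode, b.root_electrode, reference_root}
    else:
        roots = {a.root_electrode, b.root_electrode}
    keep = np.array([int(e) not in roots for e in common])
    w_int = np.where(keep, w, 0.0)
    if w_int.sum() <= 0:
        return False, np.inf
    d = np.minimum(np.abs(ia - ib), params.interval_clip)
    valid = np.isfinite(d)
    di = float(
        np.sum(np.where(valid, d, 0.0) * np.where(valid, w_int, 0.0))
        / max(np.where(valid, w_int, 0.0).sum(), 1e-12)
    )
    if di > params.max_interval_diff:
        return False, np.inf
    aa = a.mean_amplitude[common]
    ab = b.mean_amplitude[common]
    mid = (np.abs(aa) + np.abs(ab)) / 2.0
    safe = mid > 1e-9
    da_vec = np.zeros(common.size)
    da_vec[safe] = 100.0 * np.abs(aa[safe] - ab[safe]) / mid[safe]
    da_vec = np.minimum(da_vec, params.amplitude_clip)
    valid_a = np.isfinite(da_vec) & np.isfinite(aa) & np.isfinite(ab)
    wa = np.where(valid_a, w, 0.0)
    if wa.sum() <= 0:
        return False, np.inf
    da = float(np.sum(np.where(valid_a, da_vec, 0.0) * wa) / wa.sum())
    if da > params.max_amplitude_diff:
        return False, np.inf
    if params.use_root_amp_merge_condition:
        ma = a.mean_amplitude[a.root_electrode]
        mb = b.mean_amplitude[b.root_electrode]
        sd = max(a.root_amplitude_sd, b.root_amplitude_sd, 1e-9)
        if abs(ma - mb) / sd > params.max_root_amp_z:
            return False, np.inf
    score = di / params.max_interval_diff + da / params.max_amplitude_diff
    return True, score


def _merge_pair(
    ctx: SortingContext,
    a: PropagationSequence,
    b: PropagationSequence,
    root: int,
) -> PropagationSequence | None:
    """Pool both sequences' member spikes and re-extract metrics at ``root``.

    Member times of the sequence whose root differs from ``root`` are
    shifted by its mean interval at ``root`` so all pooled times live on
    the reference root's clock.
    """
    def shifted(seq: PropagationSequence) -> np.ndarray:
        if seq.root_electrode == root:
            return seq.member_times
        off = seq.mean_interval[root]
        if not np.isfinite(off):
            off = 0.0
        return seq.member_times + int(round(off))

    times = np.unique(np.concatenate([shifted(a), shifted(b)]))
    prelim = PreliminarySequence(
        root_electrode=root,
        member_times=times,
        splitting_electrodes=sorted(
            set(a.splitting_electrodes) | set(b.splitting_electrodes) | {root}
        ),
    )
    return extract_metrics(ctx, prelim, sequence_id=min(a.sequence_id, b.sequence_id))


def _greedy_merge_round(
    ctx: SortingContext,
    seqs: list[PropagationSequence],
    pair_ok,
    reference_for,
) -> list[PropagationSequence]:
    seqs = list(seqs)
    while True:
        best = None
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                if not pair_ok(seqs[i], seqs[j]):
                    continue
                ref = reference_for(seqs[i], seqs[j])
                ok, score = merge_eligible(
                    seqs[i], seqs[j], ctx.params,
                    reference_root=None if ref is None else ref,
                )
                if ok and (best is None or score < best[0]):
                    best = (score, i, j, ref)
        if best is None:
            return seqs
        _, i, j, ref = best
        root = ref if ref is not None else seqs[i].root_electrode
        merged = _merge_pair(ctx, seqs[i], seqs[j], root)
        survivors = [s for k, s in enumerate(seqs) if k not in (i, j)]
        if merged is not None:
            survivors.append(merged)
        else:
            # merged pool failed the electrode rules; keep the larger half
            survivors.append(
                seqs[i] if seqs[i].n_members >= seqs[j].n_members else seqs[j]
            )
        seqs = survivors


def relocate_root(
    ctx: SortingContext, seq: PropagationSequence
) -> PropagationSequence:
    """Move the root to an earlier electrode on the propagation path.

    A loose electrode qualifies when its mean amplitude reaches 80 % of
    the root's, its median score exceeds the stringent threshold and its
    mean interval is below −2 frames; the most negative interval wins.
    Intervals are re-referenced to the new root.
    """
    p = ctx.params
    root = seq.root_electrode
    root_amp = abs(seq.mean_amplitude[root])
    best_e, best_iv = None, np.inf
    for e in seq.loose:
        e = int(e)
        if e == root:
            continue
        iv = seq.mean_interval[e]
        if not np.isfinite(iv) or iv >= p.relocation_max_interval:
            continue
        if abs(seq.mean_amplitude[e]) < p.relocation_min_amp_fraction * root_amp:
            continue
        if seq.median_score[e] <= p.stringent_threshold:
            continue
        if iv < best_iv:
            best_e, best_iv = e, iv
    if best_e is None:
        return seq
    return _rereference(ctx, seq, best_e)


def _rereference(
    ctx: SortingContext, seq: PropagationSequence, new_root: int
) -> PropagationSequence:
    off = seq.mean_interval[new_root]
    mean_interval = seq.mean_interval - off
    times = seq.member_times + int(round(off))
    w = ctx.frames(ctx.params.propagation_window_ms)
    _, frames = _window_peak(ctx, times, np.asarray([new_root]), w)
    amps = _amplitudes_at(ctx, new_root, frames[:, 0])
    geom = ctx.geometry
    il_mask = np.array(
        [geom.distance(new_root, int(e)) <= ctx.params.inner_radius_um for e in seq.loose]
    )
    return replace(
        seq,
        root_electrode=new_root,
        member_times=times,
        mean_interval=mean_interval,
        inner_loose=seq.loose[il_mask],
        root_amplitude_sd=float(np.nanstd(amps)),
        member_root_amplitudes=amps,
    )


def merge_all(
    ctx: SortingContext, sequences: list[PropagationSequence]
) -> list[PropagationSequence]:
    """Two greedy merge rounds plus root handling.

    Round 1 merges sequences sharing a root electrode; roots are then
    relocated upstream; round 2 merges sequences whose roots are inner
    electrodes of each other, referenced to the higher-amplitude root.
    Finally each sequence's root moves to its highest-median-score
    electrode and intervals are re-referenced.
    """
    geom = ctx.geometry
    p = ctx.params

    round1 = _greedy_merge_round(
        ctx,
        sequences,
        pair_ok=lambda a, b: a.root_electrode == b.root_electrode,
        reference_for=lambda a, b: None,
    )
    relocated = [relocate_root(ctx, s) for s in round1]

    def round2_ok(a, b):
        if a.root_electrode == b.root_electrode:
            return True
        return (
            geom.distance(a.root_electrode, b.root_electrode)
            <= p.inner_radius_um
        )

    def round2_ref(a, b):
        if a.root_electrode == b.root_electrode:
            return None
        ma = abs(a.mean_amplitude[a.root_electrode])
        mb = abs(b.mean_amplitude[b.root_electrode])
        return a.root_electrode if ma >= mb else b.root_electrode

    round2 = _greedy_merge_round(ctx, relocated, round2_ok, round2_ref)

    final = []
    for s in round2:
        best = int(s.footprint[np.argmax(s.median_score[s.footprint])])
        if best != s.root_electrode and np.isfinite(s.mean_interval[best]):
            s = _rereference(ctx, s, best)
        final.append(s)
    for i, s in enumerate(final):
        s.sequence_id = i
    return final


# ----------------------------------------------------------------- reassignment
def reassign_all(
    ctx: SortingContext,
    sequences: list[PropagationSequence],
    mutually_inner_dedup: bool = True,
    update_metrics: bool = True,
) -> tuple[list[PropagationSequence], dict[int, np.ndarray]]:
    """Assign every stringent root detection to its best sequence.

    Returns the retained sequences (metrics recomputed from the assigned
    spikes when ``update_metrics``) and the spike trains per sequence id.
    Sequences ending with fewer than 10 spikes or below 0.05 Hz are
    dropped.
    """
    p = ctx.params
    frames_dedup = ctx.frames(p.dedup_window_ms)
    entries = []
    for seq in sequences:
        ev = ctx.events[seq.root_electrode]
        if ev.stringent_frames.size == 0:
            continue
        table = sequence_spike_table(ctx, seq, ev.stringent_frames)
        ok, score = _bulk_scores(ctx, seq, table)
        for t, s in zip(table["times"][ok], score[ok]):
            entries.append(
                {
                    "sequence_id": seq.sequence_id,
                    "root": seq.root_electrode,
                    "time": int(t),
                    "score": float(s),
                }
            )
    accepted = resolve_duplicates(
        entries, p, frames_dedup, ctx.geometry, mutually_inner_dedup
    )
    trains: dict[int, list[int]] = {s.sequence_id: [] for s in sequences}
    for c in accepted:
        trains[c["sequence_id"]].append(c["time"])
    duration = ctx.recording.duration_s
    kept = []
    out: dict[int, np.ndarray] = {}
    for seq in sequences:
        times = np.asarray(sorted(trains[seq.sequence_id]), dtype=np.int64)
        if times.size < p.min_spikes or times.size / duration < p.min_rate_hz:
            continue
        if update_metrics:
            prelim = PreliminarySequence(
                root_electrode=seq.root_electrode,
                member_times=times,
                splitting_electrodes=seq.splitting_electrodes,
            )
            m = extract_metrics(ctx, prelim, sequence_id=seq.sequence_id)
            if m is None:
                continue
            kept.append(m)
        else:
            kept.append(replace(seq, member_times=times))
        out[seq.sequence_id] = times
    return kept, out
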