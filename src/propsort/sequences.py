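"""Offline propagation-sequence detection.

From per-electrode detection scores to *preliminary propagation sequences*
— candidate neurons identified by their recurring sub-millisecond detection
order across adjacent electrodes:

1.  **Root detections**: stringent detections that carry the locally
    largest standardized amplitude (no larger co-detection within ±0.5 ms
    on any electrode within 100 μm) and at least one stringent
    co-detection within ±0.1 ms on an electrode within 50 μm.  Frames where
    a large fraction of the array detects simultaneously are discarded as
    electrical noise.
2.  **Interval splitting**: for each root electrode, the signed frame
    intervals between root detections and co-detections on each nearby
    "splitting" electrode are clustered with 1–4-component Gaussian
    mixtures selected by BIC; distinct interval modes separate neurons that
    share a root electrode.
3.  **Growth**: splitting electrodes are visited in ascending distance;
    clusters branch recursively, the electrode list expands along the axon
    when most detections travel together, and a patience counter stops
    growth after six consecutive distance tiers without structure.
4.  **Amplitude splitting**: a preliminary sequence whose root-amplitude
    distribution fails Hartigan's dip test (P < 0.1) is split by a 2–4
    component mixture.
5.  **Metric extraction**: per-electrode median detection scores, mean
    interelectrode intervals and mean standardized amplitudes over the
    member spikes define the sequence's loose / inner-loose / footprint
    electrode sets and its assignment statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .detector.infer import DetectionScores, detect_events
from .params import Params
from .probe import ProbeGeometry
from .recording import Recording, standardized_amplitudes
from .stats.dip import dip_test

import warnings

__all__ = [
    "ElectrodeEvents",
    "SortingContext",
    "PreliminarySequence",
    "PropagationSequence",
    "build_context",
    "find_root_detections",
    "codetection_intervals",
    "split_intervals",
    "grow_sequences",
    "amplitude_split",
    "extract_metrics",
    "detect_sequences",
]


# --------------------------------------------------------------------- events
@dataclass
class ElectrodeEvents:
    """Per-electrode detection events extracted from a score trace."""

    loose_frames: np.ndarray
    loose_scores: np.ndarray
    stringent_frames: np.ndarray
    stringent_scores: np.ndarray
    stringent_amplitudes: np.ndarray  # standardized, typically negative


@dataclass
class SortingContext:
    """Everything the sequence detector needs, precomputed once."""

    recording: Recording
    scores: DetectionScores
    params: Params
    events: list[ElectrodeEvents]
    inner: list[list[int]]  # neighbors within 50 μm per electrode
    outer: list[list[int]]  # neighbors within 100 μm per electrode

    @property
    def geometry(self) -> ProbeGeometry:
        return self.recording.geometry

    def frames(self, ms: float) -> int:
        return self.recording.ms_to_frames(ms)


def build_context(
    recording: Recording, scores: DetectionScores, params: Params
) -> SortingContext:
    """Extract loose/stringent events and their standardized amplitudes."""
    nms = recording.ms_to_frames(0.5)
    events = []
    for e in range(recording.n_electrodes):
        frames = detect_events(scores.scores[:, e], params.loose_threshold, nms)
        sc = scores.scores[frames, e]
        s_mask = sc > params.stringent_threshold
        s_frames = frames[s_mask]
        amps = standardized_amplitudes(
            recording.traces[:, e], s_frames, recording.sampling_rate
        )
        ok = np.isfinite(amps)  # drop events with too little history
        events.append(
            ElectrodeEvents(
                loose_frames=frames,
                loose_scores=sc,
                stringent_frames=s_frames[ok],
                stringent_scores=sc[s_mask][ok],
                stringent_amplitudes=amps[ok],
            )
        )
    geom = recording.geometry
    inner = [geom.neighbors(e, params.inner_radius_um) for e in range(geom.n_electrodes)]
    outer = [geom.neighbors(e, params.outer_radius_um) for e in range(geom.n_electrodes)]
    return SortingContext(recording, scores, params, events, inner, outer)


# ----------------------------------------------------------- root detections
def find_root_detections(ctx: SortingContext) -> dict[int, np.ndarray]:
    """Root detection frames per electrode.

    A root detection is a stringent detection whose standardized amplitude
    magnitude is not exceeded within ±0.5 ms on any outer electrode, with
    the required stringent co-detection within ±0.1 ms on an inner
    electrode.  Simultaneous-detection noise frames are removed first and
    electrodes below the minimum firing rate are dropped.
    """
    p = ctx.params
    n_elec = ctx.recording.n_electrodes
    w_prop = ctx.frames(p.propagation_window_ms)
    w_co = ctx.frames(0.1)
    min_elec = p.min_elec_noise(n_elec)

    # noise frames: too many simultaneous stringent detections
    all_frames = np.concatenate(
        [ev.stringent_frames for ev in ctx.events]
    ) if n_elec else np.empty(0, np.int64)
    noise_frames: set[int] = set()
    if all_frames.size:
        uniq, counts = np.unique(all_frames, return_counts=True)
        noise_frames = set(uniq[counts >= min_elec].tolist())

    duration = ctx.recording.duration_s
    out: dict[int, np.ndarray] = {}
    for e in range(n_elec):
        ev = ctx.events[e]
        keep = []
        for t, a in zip(ev.stringent_frames, ev.stringent_amplitudes):
            if int(t) in noise_frames:
                continue
            mag = abs(a)
            dominated = False
            for o in ctx.outer[e]:
                oe = ctx.events[o]
                i0 = np.searchsorted(oe.stringent_frames, t - w_prop)
                i1 = np.searchsorted(oe.stringent_frames, t + w_prop, side="right")
                if i1 > i0 and np.any(
                    np.abs(oe.stringent_amplitudes[i0:i1]) > mag
                ):
                    dominated = True
                    break
            if dominated:
                continue
            n_co = 0
            for o in ctx.inner[e]:
                oe = ctx.events[o]
                i0 = np.searchsorted(oe.stringent_frames, t - w_co)
                i1 = np.searchsorted(oe.stringent_frames, t + w_co, side="right")
                if i1 > i0:
                    n_co += 1
                    if n_co >= p.stringent_codetection_threshold - 1:
                        break
            if n_co >= p.stringent_codetection_threshold - 1:
                keep.append(int(t))
        frames = np.asarray(keep, dtype=np.int64)
        if frames.size / duration >= p.min_rate_hz and frames.size:
            out[e] = frames
    return out


# --------------------------------------------------------------- codetection
def codetection_intervals(
    root_times: np.ndarray,
    splitting_frames: np.ndarray,
    window_frames: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Match root detections to co-detections on a splitting electrode.

    Each root detection takes at most one co-detection (nearest first, each
    splitting detection consumed once).  Returns ``(matched_root_indices,
    signed_intervals)`` with intervals = splitting − root in frames.
    """
    root_times = np.asarray(root_times, dtype=np.int64)
    splitting_frames = np.asarray(splitting_frames, dtype=np.int64)
    if root_times.size == 0 or splitting_frames.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.float64)
    cand = []
    lo = np.searchsorted(splitting_frames, root_times - window_frames)
    hi = np.searchsorted(splitting_frames, root_times + window_frames, side="right")
    for i in range(root_times.size):
        for j in range(lo[i], hi[i]):
            cand.append(
                (abs(int(splitting_frames[j]) - int(root_times[i])), i, j)
            )
    cand.sort()
    used_r = np.zeros(root_times.size, bool)
    used_s = np.zeros(splitting_frames.size, bool)
    idx, iv = [], []
    for _, i, j in cand:
        if not used_r[i] and not used_s[j]:
            used_r[i] = True
            used_s[j] = True
            idx.append(i)
            iv.append(float(splitting_frames[j] - root_times[i]))
    order = np.argsort(idx)
    return (
        np.asarray(idx, np.int64)[order],
        np.asarray(iv, np.float64)[order],
    )


# ------------------------------------------------------------ GMM splitting
def _fit_gmm_bic(x: np.ndarray, k: int, seed: int = 0, reg_covar: float = 1e-6):
    """Fit a k-component 1-D Gaussian mixture; (model, BIC) or (None, nan).

    The tiny covariance floor matters on lattice-valued data (intervals
    are integer frames): a component collapsing onto a single lattice
    level then reaches a huge likelihood and a strongly *negative* BIC,
    which the negative-BIC overfitting guard discards.  A larger floor
    would instead let such fits win the comparison spuriously.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm = GaussianMixture(
                n_components=k,
                n_init=10,
                random_state=seed,
                covariance_type="full",
                reg_covar=reg_covar,
            )
            gm.fit(x)
            bic = gm.bic(x)
        if not np.isfinite(bic) or not np.all(np.isfinite(gm.means_)):
            return None, np.nan
        return gm, float(bic)
    except (FloatingPointError, ValueError, np.linalg.LinAlgError):
        return None, np.nan


def split_intervals(
    intervals: np.ndarray, params: Params, seed: int = 0
) -> list[np.ndarray]:
    """Partition an interval sample into clusters via BIC-selected mixtures.

    Mixtures with 1..4 components are fit on the dequantized sample (see
    below); models with negative BIC (overfitting guard) or numerical
    failures are ignored; if every model is ignored the single-component
    model is used.  Clusters smaller than max(10, 10 % of the sample) are
    discarded; if no cluster survives the sample stays together unsplit.

    Returns a list of index arrays into ``intervals`` (surviving clusters).
    """
    intervals = np.asarray(intervals, dtype=np.float64)
    n = intervals.size
    if n == 0:
        return []
    all_idx = np.arange(n)
    min_size = params.min_cluster_size(n)
    # intervals are quantized to whole frames; dequantization jitter keeps
    # mixture components from collapsing onto single lattice levels
    jitter = np.random.default_rng(seed).uniform(-0.5, 0.5, n)
    x = (intervals + jitter).reshape(-1, 1)
    best = None
    best_bic = np.inf
    for k in range(1, min(params.max_gmm_components, n) + 1):
        gm, bic = _fit_gmm_bic(x, k, seed)
        if gm is None or bic < 0:
            continue
        if bic < best_bic:
            best, best_bic = gm, bic
    if best is None:
        labels = np.zeros(n, dtype=int)
        means = {0: 0.0}
    else:
        labels = best.predict(x)
        means = {c: float(best.means_[c, 0]) for c in np.unique(labels)}
    # components whose means differ by ~a frame are below the timing
    # resolution that spike assignment can exploit (the weighted interval
    # thresholds are 2.5–3.5 frames): treat them as one mode
    min_mode_gap = 2.0
    comp = {c: c for c in means}
    items = sorted(means.items(), key=lambda kv: kv[1])
    for (c1, m1), (c2, m2) in zip(items, items[1:]):
        if m2 - m1 <= min_mode_gap:
            root1 = comp[c1]
            for c, r in comp.items():
                if r == comp[c2]:
                    comp[c] = root1
            comp[c2] = root1
    merged = np.array([comp[int(c)] for c in labels])
    clusters = [all_idx[merged == c] for c in np.unique(merged)]
    surviving = [c for c in clusters if c.size >= min_size]
    if not surviving:
        return [all_idx] if n >= 1 else []
    return sorted(surviving, key=lambda c: -c.size)


# -------------------------------------------------------------------- growth
@dataclass
class PreliminarySequence:
    root_electrode: int
    member_times: np.ndarray  # root-detection frames
    splitting_electrodes: list[int] = field(default_factory=list)


@dataclass
class _Branch:
    times: np.ndarray
    entries: list[tuple[float, int]]  # (tier distance, electrode)
    idx: int
    patience: int
    path: list[int]
    tier_start_dist: float | None = None
    tier_had_split: bool = False


def _compare(ctx, times, elec, seed):
    """One cluster-vs-electrode comparison.

    Returns ``(surviving_member_arrays, rejected_times, substantive)``:
    surviving arrays are member-time subsets (empty list when the cluster
    stays together untouched).
    """
    p = ctx.params
    w = ctx.frames(p.propagation_window_ms)
    idx, iv = codetection_intervals(
        times, ctx.events[elec].stringent_frames, w
    )
    if idx.size == 0:
        return [], np.empty(0, np.int64), False
    clusters = split_intervals(iv, p, seed)
    min_size = p.min_cluster_size(idx.size)
    surviving = [c for c in clusters if c.size >= min_size]
    if not surviving:
        return [], np.empty(0, np.int64), False
    member_sets = [times[idx[c]] for c in surviving]
    kept = np.concatenate([idx[c] for c in surviving])
    rejected = np.setdiff1d(times, times[kept])
    return member_sets, rejected, True


def _expansion_entries(ctx, elec, existing: set[int]) -> list[tuple[float, int]]:
    geom = ctx.geometry
    out = []
    for o in ctx.inner[elec]:
        if o not in existing:
            out.append((round(geom.distance(elec, o), 6), o))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def grow_sequences(
    ctx: SortingContext,
    root_detections: dict[int, np.ndarray],
    seed: int = 0,
) -> list[PreliminarySequence]:
    """Branching growth of preliminary sequences from every root electrode.

    Splitting electrodes are visited in ascending distance from the root
    (ties by id).  A comparison that leaves the cluster membership intact
    counts towards the patience counter of its equal-distance tier; any
    membership change resets it.  When at least half of a cluster's
    detections travel together through a splitting electrode, that
    electrode's own inner electrodes are appended to the branch's list, so
    sequences can follow axons beyond the root's immediate neighborhood.
    Root detections rejected from a branch return to the root electrode's
    pool and may seed clusters on later splitting electrodes.
    """
    p = ctx.params
    geom = ctx.geometry
    results: list[PreliminarySequence] = []

    for root in sorted(root_detections):
        base = [
            (round(geom.distance(root, o), 6), o) for o in ctx.inner[root]
        ]
        base.sort(key=lambda t: (t[0], t[1]))
        pool = np.sort(root_detections[root])
        i = 0
        while i < len(base) and pool.size >= p.n_split:
            dist_i, elec = base[i]
            pre_size = pool.size
            member_sets, rejected, substantive = _compare(ctx, pool, elec, seed)
            if substantive:
                pool = rejected
                for times in member_sets:
                    expand = times.size >= p.expansion_threshold * pre_size
                    entries = list(base)
                    if expand:
                        existing = {e for _, e in entries} | {root}
                        entries.extend(_expansion_entries(ctx, elec, existing))
                    branch = _Branch(
                        times=times,
                        entries=entries,
                        idx=i + 1,
                        patience=0,
                        path=[root, elec],
                    )
                    finished, stragglers = _refine(ctx, branch, seed)
                    results.extend(
                        PreliminarySequence(root, t, path)
                        for t, path in finished
                    )
                    if stragglers.size:
                        pool = np.sort(np.concatenate([pool, stragglers]))
            i += 1
    return results


def _refine(ctx, branch: _Branch, seed: int):
    """Iteratively refine one branch; returns (finished, rejected_times)."""
    p = ctx.params
    finished: list[tuple[np.ndarray, list[int]]] = []
    rejected_all: list[np.ndarray] = []
    stack = [branch]
    while stack:
        br = stack.pop()
        times = br.times
        idx = br.idx
        patience = br.patience
        entries = br.entries
        tier_dist = None
        tier_split = False
        while idx < len(entries) and patience < p.patience:
            dist, elec = entries[idx]
            if tier_dist is None:
                tier_dist = dist
            elif dist != tier_dist:
                # close the previous equal-distance tier
                if not tier_split:
                    patience += 1
                tier_dist = dist
                tier_split = False
                if patience >= p.patience:
                    break
            member_sets, rej, substantive = _compare(ctx, times, elec, seed)
            if substantive:
                changed = not (
                    len(member_sets) == 1
                    and member_sets[0].size == times.size
                )
                if rej.size:
                    rejected_all.append(rej)
                if changed:
                    tier_split = True
                    patience = 0
                pre_size = times.size
                if len(member_sets) > 1:
                    # branch: children continue independently
                    for t in member_sets:
                        child_entries = list(entries)
                        if t.size >= p.expansion_threshold * pre_size:
                            existing = {e for _, e in child_entries} | {
                                br.path[0]
                            }
                            child_entries.extend(
                                _expansion_entries(ctx, elec, existing)
                            )
                        stack.append(
                            _Branch(
                                times=t,
                                entries=child_entries,
                                idx=idx + 1,
                                patience=0,
                                path=br.path + [elec],
                            )
                        )
                    times = None
                    break
                times = member_sets[0]
                if elec not in br.path:
                    br.path.append(elec)
                if times.size >= p.expansion_threshold * pre_size:
                    existing = {e for _, e in entries} | {br.path[0]}
                    entries = entries + _expansion_entries(ctx, elec, existing)
            idx += 1
        if times is not None and times.size >= p.min_spikes:
            finished.append((times, br.path))
        elif times is not None and times.size:
            rejected_all.append(times)
    rejected = (
        np.sort(np.concatenate(rejected_all))
        if rejected_all
        else np.empty(0, np.int64)
    )
    return finished, rejected


# --------------------------------------------------------- amplitude splitting
def amplitude_split(
    ctx: SortingContext,
    seq: PreliminarySequence,
    seed: int = 0,
) -> list[PreliminarySequence]:
    """Split a preliminary sequence whose root-amplitude distribution is
    multimodal (dip test P < 0.1) using a BIC-selected 2–4 component
    mixture; post-split sequences below the minimum spike count are
    dropped."""
    p = ctx.params
    ev = ctx.events[seq.root_electrode]
    pos = np.searchsorted(ev.stringent_frames, seq.member_times)
    pos = np.clip(pos, 0, max(ev.stringent_frames.size - 1, 0))
    amps = ev.stringent_amplitudes[pos]
    if amps.size < 2 * p.min_spikes:
        return [seq]
    _, pval = dip_test(amps, seed=seed + 12345)
    if pval >= p.hartigan_p:
        return [seq]
    x = amps.reshape(-1, 1)
    best, best_bic = None, np.inf
    for k in range(2, min(p.max_gmm_components, amps.size) + 1):
        gm, bic = _fit_gmm_bic(x, k, seed)
        if gm is not None and bic < best_bic:
            best, best_bic = gm, bic
    if best is None:
        return [seq]
    labels = best.predict(x)
    out = []
    for c in np.unique(labels):
        times = seq.member_times[labels == c]
        if times.size >= p.min_spikes:
            out.append(
                PreliminarySequence(
                    seq.root_electrode, times, list(seq.splitting_electrodes)
                )
            )
    return out if out else [seq]


# ----------------------------------------------------------- metric extraction
@dataclass
class PropagationSequence:
    """A finalized sequence: electrode sets and per-electrode statistics.

    ``median_score`` is dense over all electrodes (0 where not computed or
    below the 3 % floor); ``mean_interval`` / ``mean_amplitude`` are dense
    with NaN outside the footprint.  Intervals are in frames relative to
    the root electrode's detection peak; amplitudes are standardized.
    """

    sequence_id: int
    root_electrode: int
    member_times: np.ndarray
    splitting_electrodes: list[int]
    loose: np.ndarray
    inner_loose: np.ndarray
    footprint: np.ndarray
    median_score: np.ndarray
    mean_interval: np.ndarray
    mean_amplitude: np.ndarray
    root_amplitude_sd: float
    member_root_amplitudes: np.ndarray

    @property
    def n_members(self) -> int:
        return self.member_times.size


def _window_peak(ctx, times, elecs, w):
    """Per member × electrode: (max score, argmax frame) in ±w frames."""
    scores = ctx.scores.scores
    n = scores.shape[0]
    offs = np.arange(-w, w + 1)
    fmat = np.clip(times[:, None] + offs[None, :], 0, n - 1)  # (m, 2w+1)
    block = scores[fmat][:, :, elecs]  # (m, 2w+1, n_e)
    arg = block.argmax(axis=1)  # (m, n_e)
    peak = np.take_along_axis(block, arg[:, None, :], axis=1)[:, 0, :]
    frames = times[:, None] + (arg - w)
    return peak, np.clip(frames, 0, n - 1)


def _amplitudes_at(ctx, elec, frames):
    return standardized_amplitudes(
        ctx.recording.traces[:, elec],
        frames,
        ctx.recording.sampling_rate,
    )


def extract_metrics(
    ctx: SortingContext,
    seq: PreliminarySequence,
    sequence_id: int = 0,
) -> PropagationSequence | None:
    """Compute a preliminary sequence's electrode sets and statistics.

    Returns None when the sequence fails the electrode-count rules (fewer
    than 4 loose / 3 inner-loose electrodes) or trips the array-wide
    loose-electrode noise filter.
    """
    p = ctx.params
    geom = ctx.geometry
    n_elec = ctx.recording.n_electrodes
    w = ctx.frames(p.propagation_window_ms)
    times = np.sort(np.asarray(seq.member_times, dtype=np.int64))
    anchors = set(seq.splitting_electrodes) | {seq.root_electrode}
    candidates = set()
    for a in anchors:
        candidates.add(a)
        candidates.update(ctx.inner[a])
    cand = np.asarray(sorted(candidates), dtype=np.int64)

    peak, _ = _window_peak(ctx, times, cand, w)
    med = np.median(peak, axis=0)
    med[med < p.min_median_score] = 0.0

    loose = cand[med > p.loose_threshold]
    if loose.size < p.min_loose:
        return None
    root = seq.root_electrode
    il_mask = np.array(
        [geom.distance(root, int(e)) <= p.inner_radius_um for e in loose]
    )
    inner_loose = loose[il_mask]
    if inner_loose.size < p.min_inner_loose:
        return None
    if int((med > p.loose_threshold).sum()) > p.min_seq_noise(n_elec):
        return None

    fp = set(int(e) for e in loose)
    for e in loose:
        fp.update(ctx.inner[int(e)])
    footprint = np.asarray(sorted(fp), dtype=np.int64)

    peak_f, frames_f = _window_peak(ctx, times, footprint, w)
    med_f = np.median(peak_f, axis=0)
    med_f[med_f < p.min_median_score] = 0.0
    root_col = int(np.flatnonzero(footprint == root)[0])
    root_arg = frames_f[:, root_col]
    intervals = frames_f - root_arg[:, None]  # (m, n_fp)
    amps = np.empty_like(intervals, dtype=np.float64)
    for c, e in enumerate(footprint):
        amps[:, c] = _amplitudes_at(ctx, int(e), frames_f[:, c])

    median_score = np.zeros(n_elec)
    median_score[footprint] = med_f
    median_score[cand] = np.maximum(median_score[cand], med)
    mean_interval = np.full(n_elec, np.nan)
    mean_interval[footprint] = intervals.mean(axis=0)
    mean_amplitude = np.full(n_elec, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_amplitude[footprint] = np.nanmean(amps, axis=0)
    root_amps = amps[:, root_col]
    return PropagationSequence(
        sequence_id=sequence_id,
        root_electrode=root,
        member_times=times,
        splitting_electrodes=list(seq.splitting_electrodes),
        loose=loose,
        inner_loose=inner_loose,
        footprint=footprint,
        median_score=median_score,
        mean_interval=mean_interval,
        mean_amplitude=mean_amplitude,
        root_amplitude_sd=float(np.nanstd(root_amps)),
        member_root_amplitudes=root_amps,
    )


def sequence_to_dict(seq: PropagationSequence) -> dict:
    """JSON-serializable record of a finalized sequence."""
    return {
        "sequence_id": int(seq.sequence_id),
        "root_electrode": int(seq.root_electrode),
        "member_times": [int(t) for t in seq.member_times],
        "splitting_electrodes": [int(e) for e in seq.splitting_electrodes],
        "loose": [int(e) for e in seq.loose],
        "inner_loose": [int(e) for e in seq.inner_loose],
        "footprint": [int(e) for e in seq.footprint],
        "median_score": seq.median_score.tolist(),
        "mean_interval": seq.mean_interval.tolist(),
        "mean_amplitude": seq.mean_amplitude.tolist(),
        "root_amplitude_sd": float(seq.root_amplitude_sd),
        "member_root_amplitudes": seq.member_root_amplitudes.tolist(),
    }


def sequence_from_dict(doc: dict) -> PropagationSequence:
    return PropagationSequence(
        sequence_id=doc["sequence_id"],
        root_electrode=doc["root_electrode"],
        member_times=np.asarray(doc["member_times"], dtype=np.int64),
        splitting_electrodes=list(doc["splitting_electrodes"]),
        loose=np.asarray(doc["loose"], dtype=np.int64),
        inner_loose=np.asarray(doc["inner_loose"], dtype=np.int64),
        footprint=np.asarray(doc["footprint"], dtype=np.int64),
        median_score=np.asarray(doc["median_score"], dtype=float),
        mean_interval=np.asarray(doc["mean_interval"], dtype=float),
        mean_amplitude=np.asarray(doc["mean_amplitude"], dtype=float),
        root_amplitude_sd=doc["root_amplitude_sd"],
        member_root_amplitudes=np.asarray(
            doc["member_root_amplitudes"], dtype=float
        ),
    )


def detect_sequences(
    recording: Recording,
    scores: DetectionScores,
    params: Params,
    seed: int = 0,
) -> tuple[list[PropagationSequence], SortingContext]:
    """Full offline sequence-detection pass (steps 1–5 above)."""
    ctx = build_context(recording, scores, params)
    roots = find_root_detections(ctx)
    prelim = grow_sequences(ctx, roots, seed)
    split = []
    for s in prelim:
        split.extend(amplitude_split(ctx, s, seed))
    final = []
    for s in split:
        m = extract_metrics(ctx, s, sequence_id=len(final))
        if m is not None:
            final.append(m)
    return final, ctx
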