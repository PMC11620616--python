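"""Spike-train and unit-level comparison metrics.

The central agreement measure between two spike trains A and B is the
overlap score

    overlap = #matches / (#A + #B − #matches)

with matches counted by greedy one-to-one pairing within 0.4 ms.  Units
from two sorters (or a sorter and ground truth) are matched by maximum
overlap (≥ 0.1); for matched units the spikes found by only one side are
compared against the co-detected spikes through per-electrode
interelectrode-interval and amplitude *difference scores*, and the per-unit
scores of the two sides are compared with a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .matching import greedy_match

__all__ = [
    "MatchResult",
    "overlap_score",
    "match_units",
    "precision_recall",
    "difference_scores",
    "paired_comparison",
]

DEFAULT_TOLERANCE_MS = 0.4
INTERVAL_CLIP_FRAMES = 7.0


@dataclass(frozen=True)
class MatchResult:
    n_matches: int
    n_a: int
    n_b: int

    @property
    def overlap(self) -> float:
        denom = self.n_a + self.n_b - self.n_matches
        return self.n_matches / denom if denom > 0 else 0.0


def overlap_score(
    train_a: np.ndarray,
    train_b: np.ndarray,
    sampling_rate: float,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> MatchResult:
    """Greedy one-to-one agreement between two sorted spike trains."""
    a = np.sort(np.asarray(train_a, dtype=np.float64))
    b = np.sort(np.asarray(train_b, dtype=np.float64))
    tol = tolerance_ms * sampling_rate / 1000.0
    pairs = greedy_match(a, b, tol)
    return MatchResult(n_matches=pairs.shape[0], n_a=a.size, n_b=b.size)


def precision_recall(
    gt_train: np.ndarray,
    detected_train: np.ndarray,
    sampling_rate: float,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> tuple[float, float]:
    """(precision, recall) of a detected train against ground truth.

    An empty detected train has undefined precision; it is reported as 1.0
    (no false positives were produced).
    """
    m = overlap_score(gt_train, detected_train, sampling_rate, tolerance_ms)
    precision = m.n_matches / m.n_b if m.n_b else 1.0
    recall = m.n_matches / m.n_a if m.n_a else 1.0
    return precision, recall


def match_units(
    units_a: dict[int, np.ndarray],
    units_b: dict[int, np.ndarray],
    sampling_rate: float,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
    min_overlap: float = 0.1,
    min_unique: int = 10,
) -> list[dict]:
    """Map units of B to their maximum-overlap counterparts in A.

    Pairs with overlap < ``min_overlap`` are not mapped.  Each returned row
    records the overlap and whether the pair qualifies for the
    difference-score analysis (≥ ``min_unique`` spikes unique to each
    side).
    """
    rows = []
    for ub, tb in units_b.items():
        best = None
        for ua, ta in units_a.items():
            m = overlap_score(ta, tb, sampling_rate, tolerance_ms)
            if best is None or m.overlap > best[1].overlap:
                best = (ua, m)
        if best is None or best[1].overlap < min_overlap:
            continue
        ua, m = best
        rows.append(
            {
                "unit_a": ua,
                "unit_b": ub,
                "overlap": m.overlap,
                "n_matches": m.n_matches,
                "n_a_only": m.n_a - m.n_matches,
                "n_b_only": m.n_b - m.n_matches,
                "difference_eligible": (
                    (m.n_a - m.n_matches) >= min_unique
                    and (m.n_b - m.n_matches) >= min_unique
                ),
            }
        )
    return rows


def difference_scores(
    matched: np.ndarray,
    a_only: np.ndarray,
    b_only: np.ndarray,
    interval_clip: float = INTERVAL_CLIP_FRAMES,
    kind: str = "interval",
) -> dict:
    """Difference scores of disputed spikes relative to co-detected spikes.

    Inputs are per-spike measurements pooled over a unit's loose electrodes
    (excluding the root): interelectrode intervals in frames or amplitudes
    in standardized units.  For each group the per-spike deviation from the
    *matched-group mean* is computed — absolute frames clipped at 7 for
    intervals, percent of the matched mean for amplitudes — and the
    matched-group mean deviation is subtracted from each group's mean
    deviation, so 0 means "as variable as the co-detected spikes".
    """
    matched = np.asarray(matched, dtype=np.float64)
    a_only = np.asarray(a_only, dtype=np.float64)
    b_only = np.asarray(b_only, dtype=np.float64)
    centre = matched.mean()

    def dev(x):
        if kind == "interval":
            return np.minimum(np.abs(x - centre), interval_clip)
        if kind == "amplitude":
            return 100.0 * np.abs(x - centre) / max(abs(centre), 1e-12)
        raise ValueError(f"unknown kind {kind!r}")

    base = dev(matched).mean()
    return {
        "matched_mean_deviation": base,
        "a_only_score": dev(a_only).mean() - base,
        "b_only_score": dev(b_only).mean() - base,
    }


def paired_comparison(
    scores_a: np.ndarray, scores_b: np.ndarray
) -> dict:
    """One-sided paired t-test: are B's per-unit scores larger than A's?

    Returns ``{"p_value", "t", "degenerate"}``; identical vectors give
    p = 0.5 (symmetric null), zero-variance nonzero differences are flagged
    degenerate with p → 0 or 1.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.size != b.size or a.size < 2:
        raise ValueError("need paired vectors of length ≥ 2")
    d = b - a
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return {"p_value": 0.5, "t": 0.0, "degenerate": True}
        return {
            "p_value": 0.0 if d.mean() > 0 else 1.0,
            "t": np.inf if d.mean() > 0 else -np.inf,
            "degenerate": True,
        }
    res = sstats.ttest_rel(b, a, alternative="greater")
    return {
        "p_value": float(res.pvalue),
        "t": float(res.statistic),
        "degenerate": False,
    }
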