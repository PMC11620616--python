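"""Probe geometry: electrode positions and radius-based neighborhood queries.

Dense arrays (≤50 μm pitch) are assumed throughout the sorter: the 50 μm
"inner" radius captures the electrodes immediately around a site (including
diagonals on a 35 μm grid, which sit at ≈49.5 μm) and the 100 μm "outer"
radius captures the next ring used for amplitude-maximum checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["ProbeGeometry", "make_probe"]


@dataclass(frozen=True)
class ProbeGeometry:
    """Electrode layout: positions in μm indexed by contiguous integer ids."""

    positions: np.ndarray  # (n_electrodes, 2) float, columns x_um, y_um
    _dist: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of x/y in μm")
        if not np.all(np.isfinite(pos)):
            raise ValueError("electrode positions must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "_dist", cdist(pos, pos))

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]

    def distance(self, a: int, b: int) -> float:
        return float(self._dist[a, b])

    def neighbors(self, electrode: int, radius: float) -> list[int]:
        """Electrode ids within ``radius`` μm of ``electrode``.

        The query electrode itself is excluded.  Results are sorted by
        ascending distance (ties broken by ascending id) and the radius
        comparison is inclusive.
        """
        if not (0 <= electrode < self.n_electrodes):
            raise KeyError(f"unknown electrode id {electrode}")
        if radius <= 0:
            raise ValueError("radius must be positive")
        d = self._dist[electrode]
        ids = np.flatnonzero((d <= radius) & (np.arange(d.size) != electrode))
        order = np.lexsort((ids, d[ids]))
        return [int(i) for i in ids[order]]

    def to_list(self) -> list[list[float]]:
        """``[[id, x, y], ...]`` schema used by metadata sidecars."""
        return [
            [int(i), float(x), float(y)]
            for i, (x, y) in enumerate(self.positions)
        ]

    @classmethod
    def from_list(cls, entries: list) -> "ProbeGeometry":
        entries = sorted(entries, key=lambda e: e[0])
        ids = [int(e[0]) for e in entries]
        if ids != list(range(len(ids))):
            raise ValueError("electrode ids must be unique and contiguous from 0")
        return cls(np.array([[e[1], e[2]] for e in entries], dtype=float))


def make_probe(kind: str, n_rows: int, n_cols: int) -> ProbeGeometry:
    """Reference probe layouts.

    ``grid35``
        Square lattice at 35 μm pitch, the MEA configuration obtained by
        selecting every other electrode of a dense array.
    ``np_checkerboard``
        Staggered two-offset layout mimicking a Neuropixels checkerboard
        channel selection (32 μm horizontal pitch, 20 μm row spacing, rows
        alternately offset by 16 μm).
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("probe dimensions must be positive")
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    rows = rows.ravel()
    cols = cols.ravel()
    if kind == "grid35":
        xy = np.column_stack([cols * 35.0, rows * 35.0])
    elif kind == "np_checkerboard":
        xy = np.column_stack([cols * 32.0 + (rows % 2) * 16.0, rows * 20.0])
    else:
        raise ValueError(f"unknown probe kind {kind!r}")
    return ProbeGeometry(xy)
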