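"""Chaos game representation of reads and multi-resolution box counting.

Each nucleotide pulls the current point halfway toward its corner of the
unit square — A=(0,0), C=(0,1), G=(1,0), T=(1,1) — starting from the
center (0.5, 0.5) independently for every read. The first few points of
each read are discarded (default 10) so that the residual influence of
the arbitrary starting point does not contaminate the box counts.

Counts are accumulated once on the finest dyadic grid (side 2^-level) and
coarser grids are obtained by exact 2x2 block summation, which is
equivalent to independent recounting at every resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ReadSet

__all__ = [
    "CGRPointCloud",
    "CountPyramid",
    "map_read",
    "build_count_pyramid",
    "pyramid_from_points",
    "render_heatmap",
    "CORNERS",
]

# corner assignment: x-bit set for G/T, y-bit set for C/T
CORNERS: dict[str, tuple[float, float]] = {
    "A": (0.0, 0.0),
    "C": (0.0, 1.0),
    "G": (1.0, 0.0),
    "T": (1.0, 1.0),
}

_MAX_LEVEL = 16

# byte -> base code lookup (A,C,G,T -> 0..3, anything else -> 255)
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_CX = np.array([0.0, 0.0, 1.0, 1.0])  # x corner per code (G,T -> 1)
_CY = np.array([0.0, 1.0, 0.0, 1.0])  # y corner per code (C,T -> 1)


@dataclass
class CGRPointCloud:
    """CGR points of a single read; coordinates lie strictly inside (0, 1)."""

    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return self.x.size

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def _encode(sequence: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def map_read(sequence: str, discard_prefix: int = 10) -> CGRPointCloud:
    """Map one read to its CGR point cloud.

    One point is emitted per A/C/G/T symbol (case-insensitive); other
    symbols (N, ambiguity codes) emit no point and leave the current
    position unchanged. The first ``discard_prefix`` emitted points are
    dropped. Degenerate inputs yield an empty cloud.
    """
    if discard_prefix < 0:
        raise ValueError("discard_prefix must be non-negative")
    empty = CGRPointCloud(np.empty(0), np.empty(0))
    if not sequence:
        return empty
    codes = _encode(sequence)
    codes = codes[codes != 255]
    n = codes.size
    if n <= discard_prefix:
        return empty
    xs = np.empty(n)
    ys = np.empty(n)
    x, y = 0.5, 0.5
    cx, cy = _CX, _CY
    for k in range(n):
        c = codes[k]
        x = (x + cx[c]) * 0.5
        y = (y + cy[c]) * 0.5
        xs[k] = x
        ys[k] = y
    return CGRPointCloud(xs[discard_prefix:], ys[discard_prefix:])


@dataclass
class CountPyramid:
    """Per-level square grids of CGR point counts over the unit square.

    ``levels[l]`` is a ``2^l x 2^l`` integer array indexed ``[row, col]``
    with ``row = floor(y * 2^l)`` and ``col = floor(x * 2^l)``; every
    stored level sums to ``total``, and each coarser grid equals the 2x2
    block sums of the next finer one.
    """

    levels: dict[int, np.ndarray] = field(default_factory=dict)
    total: int = 0
    _occupied: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def max_level(self) -> int:
        return max(self.levels)

    def level(self, level: int) -> np.ndarray:
        if level not in self.levels:
            raise KeyError(f"level {level} not stored (have {sorted(self.levels)})")
        return self.levels[level]

    def occupied_counts(self, level: int) -> np.ndarray:
        """Counts of the occupied cells at ``level`` (order unspecified).

        The partition sums only depend on these values; a cache filled
        during construction avoids rescanning the dense grids.
        """
        if level not in self._occupied:
            grid = self.level(level).ravel()
            self._occupied[level] = grid[grid > 0]
        return self._occupied[level]

    def validate(self) -> None:
        """Check conservation and dyadic-aggregation invariants (for tests)."""
        for lv, grid in self.levels.items():
            if grid.shape != (2**lv, 2**lv):
                raise AssertionError(f"level {lv} grid has shape {grid.shape}")
            if int(grid.sum()) != self.total:
                raise AssertionError(f"level {lv} sum != total")
            finer = self.levels.get(lv + 1)
            if finer is not None:
                agg = finer.reshape(2**lv, 2, 2**lv, 2).sum(axis=(1, 3))
                if not np.array_equal(agg, grid):
                    raise AssertionError(f"level {lv} != block sums of level {lv + 1}")

    def to_records(self) -> "np.ndarray":
        """Nonzero cells as a structured array of (level, row, col, count)."""
        recs = []
        for lv in sorted(self.levels):
            rows, cols = np.nonzero(self.levels[lv])
            counts = self.levels[lv][rows, cols]
            recs.append(
                np.rec.fromarrays(
                    [np.full(rows.size, lv), rows, cols, counts],
                    names=["level", "row", "col", "count"],
                )
            )
        return np.concatenate(recs) if recs else np.rec.fromarrays([[], [], [], []], names=["level", "row", "col", "count"])

    def save_tsv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(self.to_records()).to_csv(path, sep="\t", index=False)
        return path


def pyramid_from_points(x: np.ndarray, y: np.ndarray, max_level: int = 13) -> CountPyramid:
    """Bin points into the finest grid and aggregate upward.

    Coordinates equal to 1.0 are clamped into the last cell (defensive:
    CGR points never reach the boundary).
    """
    if not 1 <= max_level <= _MAX_LEVEL:
        raise ValueError(f"max_level must be in [1, {_MAX_LEVEL}]")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty point cloud")
    side = 1 << max_level
    col = np.clip((x * side).astype(np.int64), 0, side - 1)
    row = np.clip((y * side).astype(np.int64), 0, side - 1)
    dtype = np.int32 if x.size < 2**31 else np.int64

    # count occupied cells sparsely, then scatter into dense grids; the
    # grids come from calloc so untouched (empty) pages stay cheap
    cells, counts = np.unique(row * side + col, return_counts=True)
    levels: dict[int, np.ndarray] = {}
    occupied: dict[int, np.ndarray] = {}
    for lv in range(max_level, 0, -1):
        occupied[lv] = counts.astype(dtype)
        grid = np.zeros(side * side, dtype=dtype)
        np.put(grid, cells, occupied[lv])
        levels[lv] = grid.reshape(side, side)
        if lv > 1:
            # dyadic aggregation on the sparse cells: parent of (r, c)
            parent = (cells // side >> 1) * (side >> 1) + ((cells % side) >> 1)
            cells, inverse = np.unique(parent, return_inverse=True)
            counts = np.bincount(inverse, weights=counts).astype(np.int64)
            side >>= 1
    return CountPyramid(levels=levels, total=int(x.size), _occupied=occupied)


def _cgr_points_batch(
    sequences: Sequence[str], discard_prefix: int
) -> tuple[np.ndarray, np.ndarray]:
    """CGR coordinates of all retained points across reads, vectorized.

    Runs the recursion position-by-position across all reads at once; the
    elementwise float operations are identical to :func:`map_read`, so the
    two paths produce bit-identical coordinates.
    """
    n = len(sequences)
    lengths = np.fromiter((len(s) for s in sequences), dtype=np.int64, count=n)
    maxlen = int(lengths.max()) if n else 0
    codes = np.full((n, maxlen), 255, dtype=np.uint8)
    for i, s in enumerate(sequences):
        codes[i, : len(s)] = _encode(s)

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    px = np.full(n, 0.5)
    py = np.full(n, 0.5)
    emitted = np.zeros(n, dtype=np.int64)
    for k in range(maxlen):
        c = codes[:, k]
        valid = c != 255
        if not valid.any():
            continue
        cc = np.where(valid, c, 0)
        nx = (px + _CX[cc]) * 0.5
        ny = (py + _CY[cc]) * 0.5
        px = np.where(valid, nx, px)
        py = np.where(valid, ny, py)
        keep = valid & (emitted >= discard_prefix)
        emitted += valid
        if keep.any():
            xs.append(px[keep])
            ys.append(py[keep])
    if not xs:
        return np.empty(0), np.empty(0)
    return np.concatenate(xs), np.concatenate(ys)


def build_count_pyramid(
    readset: ReadSet | Sequence[str],
    max_level: int = 13,
    discard_prefix: int = 10,
) -> CountPyramid:
    """Map every read through the CGR and accumulate the count pyramid.

    ``total`` equals the number of retained points: per read,
    ``max(0, #ACGT symbols - discard_prefix)``. Raises if no point
    survives the prefix discard.
    """
    sequences = readset.sequences if isinstance(readset, ReadSet) else list(readset)
    if not sequences:
        raise ValueError("empty read set")
    x, y = _cgr_points_batch(sequences, discard_prefix)
    if x.size == 0:
        raise ValueError("empty point cloud: no read yields points after the prefix discard")
    return pyramid_from_points(x, y, max_level=max_level)


def render_heatmap(
    pyramid: CountPyramid, level: int, cap_multiplier: float = 3.0
) -> np.ndarray:
    """Counts at ``level`` with values capped at ``cap_multiplier * mean``.

    Dense cells dominate the color scale otherwise; the cap is a display
    convention, not a change to the stored counts. Returns a float matrix;
    writing it to PNG/SVG is a thin wrapper (see the ``cgr`` CLI command).
    """
    grid = pyramid.level(level).astype(float)
    cap = cap_multiplier * grid.mean()
    return np.minimum(grid, cap)


def save_heatmap_png(matrix: np.ndarray, path: str | Path, cmap: str = "viridis") -> Path:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    # origin lower-left so A=(0,0) appears bottom-left as in the unit square
    plt.imsave(path, matrix, cmap=cmap, origin="lower")
    return path
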