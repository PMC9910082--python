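"""Generalized (Rényi) dimension spectrum D(q) from box-count pyramids.

For a measure resolved on dyadic grids of side eps = 2^-l, the partition
sum  sum_i M_i^q  over occupied boxes scales as a power of eps; the slope
s(q) of its logarithm against ln(eps), estimated by ordinary least
squares over a ladder of levels, gives

    D(q) = s(q) / (q - 1)          (q != 1)
    D(1) = slope of sum_i (M_i/M_0) ln(M_i/M_0) against ln(eps)

so that a uniform filling of the square has D(q) = 2 for every q, D(0)
is the box-counting dimension of the support, D(1) the information
dimension and D(2) the correlation dimension. D(q) is non-increasing in
q. Negative q amplifies the sampling noise of nearly-empty boxes and is
rejected by default; a flag allows it for exploration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cgr import CountPyramid

__all__ = [
    "MultifractalSpectrum",
    "log_partition_sum",
    "fit_generalized_dimension",
    "compute_spectrum",
    "default_q_grid",
    "default_levels",
    "binomial_cascade_weights",
]

_Q1_TOL = 1e-9
DEFAULT_LEVELS: tuple[int, ...] = (6, 7, 8, 10, 11, 12, 13)


def default_q_grid() -> np.ndarray:
    """The standard q ladder: 0 to 15 in steps of 0.2 (76 values)."""
    return np.round(np.linspace(0.0, 15.0, 76), 9)


def default_levels() -> tuple[int, ...]:
    return DEFAULT_LEVELS


@dataclass
class MultifractalSpectrum:
    """q grid, fitted D(q) values and per-q goodness of fit."""

    q_values: np.ndarray
    dimensions: np.ndarray
    fit_r2: np.ndarray
    epsilon_levels: tuple[int, ...]

    def __post_init__(self) -> None:
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.dimensions = np.asarray(self.dimensions, dtype=float)
        self.fit_r2 = np.asarray(self.fit_r2, dtype=float)
        if not (self.q_values.size == self.dimensions.size == self.fit_r2.size):
            raise ValueError("q_values, dimensions, fit_r2 must have equal length")
        if np.any(np.diff(self.q_values) <= 0):
            raise ValueError("q_values must be strictly increasing")
        if not np.all(np.isfinite(self.dimensions)):
            raise ValueError("non-finite dimension in spectrum")

    def __len__(self) -> int:
        return self.q_values.size

    def dimension_at(self, q: float) -> float:
        idx = np.nonzero(np.isclose(self.q_values, q))[0]
        if idx.size == 0:
            raise KeyError(f"q={q} not in spectrum grid")
        return float(self.dimensions[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"q": self.q_values, "D": self.dimensions, "r_squared": self.fit_r2}
        )

    def save_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def log_partition_sum(grid: np.ndarray, total: float, q: float) -> float:
    """Log partition sum of one grid at moment order ``q``.

    For ``q != 1`` returns ``ln(sum over occupied cells of M_i^q)``;
    empty cells contribute nothing, including at q = 0 where each
    occupied cell contributes 1 (0^0 is treated as 0). For ``q == 1``
    (within 1e-9) returns ``sum (M_i/total) ln(M_i/total)``, the
    information-dimension branch. ``grid`` may hold integer counts or
    non-negative analytic weights; ``total`` is the normalizer M_0.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    values = np.asarray(grid, dtype=float).ravel()
    if np.any(values < 0):
        raise ValueError("negative cell value")
    occupied = values[values > 0]
    if occupied.size == 0:
        raise ValueError("no occupied cells")
    if abs(q - 1.0) < _Q1_TOL:
        p = occupied / total
        return float(np.sum(p * np.log(p)))
    if q == 0:
        return float(np.log(occupied.size))
    return float(logsumexp(q * np.log(occupied)))


def fit_generalized_dimension(
    per_level_sums: Sequence[tuple[float, float]], q: float
) -> tuple[float, float]:
    """OLS fit of partition values against ln(eps); returns (D, r2).

    ``per_level_sums`` pairs ln(eps) with the partition value at that
    resolution (the output of :func:`log_partition_sum`). The slope is
    divided by (q - 1) except on the q = 1 branch where it is the
    dimension itself. ``r2`` is the squared correlation of the fit; a
    constant sequence fits perfectly with slope 0 and r2 = 1.
    """
    if len(per_level_sums) < 3:
        raise ValueError("need at least 3 resolution levels to fit")
    x = np.array([p[0] for p in per_level_sums], dtype=float)
    y = np.array([p[1] for p in per_level_sums], dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("degenerate fit: identical ln(eps) values")
    slope = float(xc @ yc) / sxx
    ss_tot = float(yc @ yc)
    resid = yc - slope * xc
    ss_res = float(resid @ resid)
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    if abs(q - 1.0) < _Q1_TOL:
        return slope, r2
    return slope / (q - 1.0), r2


def _compress_level(occupied: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct occupied count values and their multiplicities.

    The partition sum only depends on the histogram of cell values, which
    collapses millions of cells to a few hundred distinct counts.
    """
    if occupied.size == 0:
        raise ValueError("no occupied cells")
    return np.unique(occupied, return_counts=True)


def _partition_values(
    values: np.ndarray, mult: np.ndarray, total: float, q_values: np.ndarray
) -> np.ndarray:
    v = values.astype(float)
    log_v = np.log(v)
    log_m = np.log(mult.astype(float))
    out = np.empty(q_values.size)
    mass = float(mult @ v)
    plogp = float(mult @ (v * log_v))
    for j, q in enumerate(q_values):
        if abs(q - 1.0) < _Q1_TOL:
            # sum (m/M0) ln(m/M0) aggregated over the value histogram
            out[j] = plogp / total - math.log(total) * mass / total
        else:
            out[j] = logsumexp(q * log_v + log_m)
    return out


def compute_spectrum(
    pyramid: CountPyramid,
    q_values: Sequence[float] | None = None,
    levels: Sequence[int] = DEFAULT_LEVELS,
    allow_negative_q: bool = False,
) -> MultifractalSpectrum:
    """Fit D(q) over a ladder of resolutions stored in ``pyramid``.

    Defaults follow the standard protocol: q from 0 to 15 in steps of
    0.2 and the seven-level eps ladder 2^-6 ... 2^-13 (2^-9 omitted).
    Negative q is rejected unless ``allow_negative_q`` is set, because
    the spectrum of sampled read sets is unstable there.
    """
    q = default_q_grid() if q_values is None else np.asarray(q_values, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q_values must be a non-empty 1-D sequence")
    if np.any(np.diff(q) <= 0):
        raise ValueError("q_values must be strictly increasing")
    if np.any(q < 0) and not allow_negative_q:
        raise ValueError(
            "negative q requested: D(q) is unstable for q < 0 on sampled point "
            "clouds; pass allow_negative_q=True to override"
        )
    levels = tuple(int(l) for l in levels)
    if len(levels) < 3:
        raise ValueError("need at least 3 levels")
    missing = [l for l in levels if l not in pyramid.levels]
    if missing:
        raise ValueError(f"levels {missing} not stored in pyramid")

    total = float(pyramid.total)
    ln_eps = np.array([-lv * math.log(2.0) for lv in levels])
    per_level = np.empty((len(levels), q.size))
    for i, lv in enumerate(levels):
        values, mult = _compress_level(pyramid.occupied_counts(lv))
        per_level[i] = _partition_values(values, mult, total, q)

    dims = np.empty(q.size)
    r2s = np.empty(q.size)
    for j in range(q.size):
        pairs = list(zip(ln_eps, per_level[:, j]))
        dims[j], r2s[j] = fit_generalized_dimension(pairs, float(q[j]))
    return MultifractalSpectrum(q, dims, r2s, levels)


def binomial_cascade_weights(level: int, p: float) -> np.ndarray:
    """1-D binomial multiplicative cascade measure resolved at ``level``.

    Mass splits p : (1-p) at every dyadic refinement; the returned vector
    of length 2^level sums to 1. The outer product of the vector with
    itself is the 2-D product cascade, whose Rényi dimensions are known
    in closed form — used as an analytic fixture for the D(q) estimator.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    w = np.array([1.0])
    for _ in range(level):
        w = np.concatenate([p * w, (1 - p) * w])
    return w
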