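"""scikit-learn style front end.

:class:`CGRMultifractal` turns read sets into D(q) feature vectors, so
the whole pipeline composes with sklearn model selection, e.g.::

    pipe = make_pipeline(CGRMultifractal(), LinearDiscriminantAnalysis())

Like a text vectorizer, its input is a list of raw samples (read sets),
not a numeric matrix; the output is an (n_samples, n_q) array.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .cgr import build_count_pyramid
from .io import ReadSet
from .multifractal import (
    DEFAULT_LEVELS,
    MultifractalSpectrum,
    compute_spectrum,
    default_q_grid,
)

__all__ = ["CGRMultifractal"]


class CGRMultifractal(TransformerMixin, BaseEstimator):
    """Transform metagenome read sets into Rényi dimension spectra D(q).

    Parameters
    ----------
    q_min, q_max, q_step:
        Moment-order grid; defaults 0 to 15 in steps of 0.2.
    levels:
        Dyadic resolution ladder used in the log-log fit (box side
        2^-level); default (6, 7, 8, 10, 11, 12, 13).
    max_level:
        Finest grid accumulated; defaults to ``max(levels)``.
    discard_prefix:
        CGR points dropped at the start of every read (default 10).

    Attributes
    ----------
    q_values_ : ndarray of shape (n_q,)
        The frozen q grid; one output column per entry.
    levels_ : tuple of int
        The resolved resolution ladder.
    """

    def __init__(
        self,
        q_min: float = 0.0,
        q_max: float = 15.0,
        q_step: float = 0.2,
        levels: Sequence[int] = DEFAULT_LEVELS,
        max_level: int | None = None,
        discard_prefix: int = 10,
    ) -> None:
        self.q_min = q_min
        self.q_max = q_max
        self.q_step = q_step
        self.levels = levels
        self.max_level = max_level
        self.discard_prefix = discard_prefix

    def _q_grid(self) -> np.ndarray:
        if (self.q_min, self.q_max, self.q_step) == (0.0, 15.0, 0.2):
            return default_q_grid()
        n = int(round((self.q_max - self.q_min) / self.q_step)) + 1
        return np.round(np.linspace(self.q_min, self.q_max, n), 9)

    def fit(self, X: Sequence[ReadSet | Sequence[str]] | None = None, y=None):
        """Freeze the q grid and resolution ladder (stateless otherwise)."""
        q = self._q_grid()
        if np.any(q < 0):
            raise ValueError("q grid must be non-negative")
        levels = tuple(int(l) for l in self.levels)
        if len(levels) < 3:
            raise ValueError("need at least 3 resolution levels")
        self.q_values_ = q
        self.levels_ = levels
        self.max_level_ = int(self.max_level) if self.max_level is not None else max(levels)
        if self.max_level_ < max(levels):
            raise ValueError("max_level smaller than the finest requested level")
        return self

    def spectrum(self, readset: ReadSet | Sequence[str]) -> MultifractalSpectrum:
        """Full spectrum (with fit diagnostics) of one read set."""
        if not hasattr(self, "q_values_"):
            self.fit()
        pyramid = build_count_pyramid(
            readset, max_level=self.max_level_, discard_prefix=self.discard_prefix
        )
        return compute_spectrum(pyramid, self.q_values_, self.levels_)

    def transform(self, X: Sequence[ReadSet | Sequence[str]]) -> np.ndarray:
        """D(q) matrix of shape (n_samples, n_q)."""
        if not hasattr(self, "q_values_"):
            raise RuntimeError("call fit before transform")
        return np.vstack([self.spectrum(sample).dimensions for sample in X])

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "q_values_"):
            self.fit()
        return np.array([f"D(q={q:g})" for q in self.q_values_], dtype=object)
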