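"""Calibrated linear quantization of real feature vectors to [1..m].

Encoder outputs are floating point; the memory registers work on
discrete functions.  The bridge is a per-feature min–max linear map
followed by rounding: values observed on the calibration corpus span
``[lo_i, hi_i]`` and are mapped onto the ``m`` integer levels
``1..m``.  Out-of-range features (test data legitimately exceeds the
calibration extremes) clamp to the nearest end level.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["LevelQuantizer", "round_half_up"]


def round_half_up(x):
    """Round with .5 going up, element-wise; deterministic across platforms."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


class LevelQuantizer(TransformerMixin, BaseEstimator):
    """Map real n-feature vectors to discrete functions on ``[1..m]``.

    The transform of feature ``i`` is::

        clamp(round_half_up(1 + (x_i - lo_i) / (hi_i - lo_i) * (m - 1)), 1, m)

    where ``lo_i``/``hi_i`` are the per-feature minima and maxima of
    the fitting corpus.  A degenerate feature (``lo_i == hi_i``) maps
    to the middle level ``round_half_up((1 + m) / 2)``.

    Parameters
    ----------
    m : int, default=64
        Number of discrete levels.

    Attributes
    ----------
    lo_, hi_ : ndarray of shape (n_features,)
        Calibration extremes.
    """

    def __init__(self, m: int = 64):
        self.m = m

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("fit needs a non-empty 2-D array of vectors")
        if self.m < 1:
            raise ValueError("m must be a positive integer")
        self.n_features_in_ = X.shape[1]
        self.lo_ = X.min(axis=0)
        self.hi_ = X.max(axis=0)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        if one_d:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        span = self.hi_ - self.lo_
        degenerate = span == 0
        safe_span = np.where(degenerate, 1.0, span)
        scaled = 1 + (X - self.lo_) / safe_span * (self.m - 1)
        # round and clamp in float space: a near-degenerate span can
        # push the scaled value past the int64 range before the clamp
        out_f = np.floor(scaled + 0.5)
        out_f = np.where(degenerate, np.floor((1 + self.m) / 2 + 0.5), out_f)
        out = np.clip(out_f, 1, self.m).astype(np.int64)
        return out[0] if one_d else out

    def inverse_transform(self, F) -> np.ndarray:
        """Map discrete levels back to representative real values.

        Level ``v`` maps to ``lo + (v - 1) / (m - 1) * (hi - lo)`` (the
        level's nominal position); with a single level, the midpoint of
        the calibration range.  Used by the synthesis path to turn a
        retrieved function back into decoder input.
        """
        check_is_fitted(self)
        F = np.asarray(F, dtype=float)
        if self.m == 1:
            shape = F.shape
            return np.broadcast_to((self.lo_ + self.hi_) / 2.0, shape).copy()
        return self.lo_ + (F - 1) / (self.m - 1) * (self.hi_ - self.lo_)

    # ------------------------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self)
        return json.dumps(
            {
                "n": int(self.n_features_in_),
                "m": int(self.m),
                "lo": self.lo_.tolist(),
                "hi": self.hi_.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LevelQuantizer":
        doc = json.loads(text)
        q = cls(m=int(doc["m"]))
        q.n_features_in_ = int(doc["n"])
        q.lo_ = np.asarray(doc["lo"], dtype=float)
        q.hi_ = np.asarray(doc["hi"], dtype=float)
        if q.lo_.shape != (q.n_features_in_,) or q.hi_.shape != (q.n_features_in_,):
            raise ValueError("calibration arrays do not match declared n")
        if np.any(q.lo_ > q.hi_):
            raise ValueError("lo must not exceed hi")
        return q
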