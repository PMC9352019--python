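"""Multi-class entropic memory: one register per class plus an entropy filter.

The classifier keeps one :class:`~entromem.core.AMRGrid` per class and
answers a query by presenting the cue to every register.  A cue accepted
by no register is *unknown* — an explicit rejection, not a forced
nearest match.  A cue accepted by several registers is assigned to the
accepting class whose register has the **smallest entropy**: the least
indeterminate memory makes the most committed claim about the cue.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .core import AMRGrid, RetrievalOutcome, as_function

logger = logging.getLogger(__name__)

#: Distinguished label returned when every register rejects the cue.
UNKNOWN = "unknown"

__all__ = ["EntropicMemoryClassifier", "QueryResult", "UNKNOWN"]


@dataclass(frozen=True)
class QueryResult:
    """Outcome of presenting one cue to the full memory system.

    ``label`` is :data:`UNKNOWN` iff no register accepted; otherwise it
    is the accepting class of minimal entropy and ``retrieved`` holds
    the function read constructively from that register.
    """

    label: object
    retrieved: np.ndarray | None
    accepting_labels: tuple
    entropies: dict = field(default_factory=dict)

    @property
    def is_unknown(self) -> bool:
        return len(self.accepting_labels) == 0


class EntropicMemoryClassifier(ClassifierMixin, BaseEstimator):
    """Associative-memory classifier with entropy-based disambiguation.

    Parameters
    ----------
    m : int, default=64
        Number of rows (discrete values) of every register.
    relaxation_k : int, default=0
        Default number of cue attributes allowed to fail recognition.
        Strict inclusion (0) is the usual classification setting;
        occlusion experiments pass small positive values explicitly.
    routing : dict or None, default=None
        Optional map from raw labels to register labels, used to store
        several raw classes in one register (e.g. a capital and its
        lower-case form).  Labels absent from the map route to
        themselves.
    random_state : int, Generator or None, default=None
        Seeds the stochastic retrieval draws made by :meth:`query`.

    Attributes
    ----------
    classes_ : ndarray
        Register labels in fixed (sorted) order; ties in the entropy
        filter resolve to the earliest label in this order.
    registers_ : dict
        Maps each register label to its :class:`AMRGrid`.
    n_features_in_ : int
        Number of attributes n of every register.

    Examples
    --------
    >>> X = [[1, 2, 4, 7], [3, 2, 6, 7], [7, 7, 1, 1]]
    >>> clf = EntropicMemoryClassifier(m=7).fit(X, ["a", "a", "b"])
    >>> clf.predict([[1, 2, 4, 7], [5, 5, 5, 5]])
    array(['a', 'unknown'], dtype=object)
    """

    def __init__(self, m=64, relaxation_k=0, routing=None, random_state=None):
        self.m = m
        self.relaxation_k = relaxation_k
        self.routing = routing
        self.random_state = random_state

    # ------------------------------------------------------------------
    def route(self, labels) -> np.ndarray:
        """Apply the label-routing map to raw labels."""
        routing = self.routing or {}
        return np.asarray([routing.get(y, y) for y in np.asarray(labels).ravel()])

    def fit(self, X, y):
        """Build one register per routed class and store every sample.

        ``X`` must be an integer array of discrete functions with
        values in ``[1, m]`` (quantize real features first, e.g. with
        :class:`~entromem.quantize.LevelQuantizer`).
        """
        X = np.asarray(X)
        y = self.route(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x attributes)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        n = X.shape[1]
        self.classes_ = np.unique(y)
        self.n_features_in_ = n
        self.registers_ = {c: AMRGrid(n, self.m) for c in self.classes_}
        for f, c in zip(X, y):
            self.registers_[c].register(as_function(f, n, self.m))
        self._rng = np.random.default_rng(self.random_state)
        return self

    def memorize(self, label, f) -> "EntropicMemoryClassifier":
        """Store one more function in the register of ``label``.

        Touches exactly one register; every other register's acceptance
        behaviour is unchanged.
        """
        check_is_fitted(self)
        label = self.route([label])[0]
        if label not in self.registers_:
            raise ValueError(f"unknown class label: {label!r}")
        self.registers_[label].register(f)
        return self

    # ------------------------------------------------------------------
    def register_entropies(self) -> dict:
        """Current entropy (bits) of every register."""
        check_is_fitted(self)
        return {c: self.registers_[c].entropy() for c in self.classes_}

    def accepting(self, X, k: int | None = None) -> np.ndarray:
        """Boolean acceptance matrix of shape (n_samples, n_classes)."""
        check_is_fitted(self)
        X = np.asarray(X)
        k = self.relaxation_k if k is None else k
        out = np.zeros((X.shape[0], len(self.classes_)), dtype=bool)
        for j, c in enumerate(self.classes_):
            out[:, j], _ = self.registers_[c].recognize_batch(X, k)
        return out

    def query(self, cue, k: int | None = None, rng=None) -> QueryResult:
        """Full query: acceptance by every register, filter, retrieval.

        The winner among multiple accepting registers is the one with
        minimal entropy, computed on current contents; an exact entropy
        tie resolves to the earliest label in ``classes_`` order (and is
        logged).  When nothing accepts, the result is *unknown* and no
        function is retrieved.
        """
        check_is_fitted(self)
        k = self.relaxation_k if k is None else k
        rng = self._rng if rng is None else rng
        cue = as_function(cue, self.n_features_in_, self.m)
        accepting = [
            c for c in self.classes_ if self.registers_[c].recognize(cue, k)[0]
        ]
        entropies = {c: self.registers_[c].entropy() for c in accepting}
        if not accepting:
            return QueryResult(UNKNOWN, None, (), {})
        best = min(entropies.values())
        winners = [c for c in accepting if entropies[c] == best]
        if len(winners) > 1:
            logger.warning(
                "entropy tie among registers %s at %.4f bits; picking %r",
                winners, best, winners[0],
            )
        winner = winners[0]
        outcome: RetrievalOutcome = self.registers_[winner].retrieve(cue, k, rng)
        return QueryResult(winner, outcome.function, tuple(accepting), entropies)

    def predict(self, X, k: int | None = None) -> np.ndarray:
        """Class label per cue, or :data:`UNKNOWN` where all registers reject.

        Deterministic: uses acceptance and the entropy filter only (no
        retrieval draws).
        """
        check_is_fitted(self)
        X = np.asarray(X)
        acc = self.accepting(X, k)
        ent = np.array([self.registers_[c].entropy() for c in self.classes_])
        out = np.full(X.shape[0], UNKNOWN, dtype=object)
        any_acc = acc.any(axis=1)
        if any_acc.any():
            masked = np.where(acc[any_acc], ent[None, :], np.inf)
            out[any_acc] = self.classes_[np.argmin(masked, axis=1)]
        return out

    def score(self, X, y, k: int | None = None) -> float:
        """Accuracy against routed labels; unknowns count as errors."""
        return float(np.mean(self.predict(X, k) == self.route(y)))

    # ------------------------------------------------------------------
    # persistence: directory of per-register JSON files plus a manifest
    def save(self, directory: str) -> None:
        check_is_fitted(self)
        os.makedirs(directory, exist_ok=True)
        manifest = {
            "labels": [str(c) for c in self.classes_],
            "n": int(self.n_features_in_),
            "m": int(self.m),
            "relaxation_k": int(self.relaxation_k),
            "routing": {str(a): str(b) for a, b in (self.routing or {}).items()},
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        for idx, c in enumerate(self.classes_):
            path = os.path.join(directory, f"register_{idx:03d}.json")
            with open(path, "w") as fh:
                fh.write(self.registers_[c].to_json())

    @classmethod
    def load(cls, directory: str) -> "EntropicMemoryClassifier":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        clf = cls(
            m=manifest["m"],
            relaxation_k=manifest.get("relaxation_k", 0),
            routing=manifest.get("routing") or None,
        )
        labels = manifest["labels"]
        clf.classes_ = np.asarray(labels, dtype=object)
        clf.n_features_in_ = manifest["n"]
        clf.registers_ = {}
        for idx, c in enumerate(labels):
            path = os.path.join(directory, f"register_{idx:03d}.json")
            with open(path) as fh:
                clf.registers_[c] = AMRGrid.from_json(fh.read())
        clf._rng = np.random.default_rng(None)
        return clf
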