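"""Associative memory registers over boolean value tables.

An :class:`AMRGrid` is an ``n x m`` boolean table: columns (arguments)
are the attributes of stored objects, rows are their ``m`` potential
discrete values, and a marked cell ``(i, j)`` states that attribute
``i`` may take value ``j``.  Individual objects are *discrete
functions* — total assignments of one value in ``[1..m]`` to each of
the ``n`` attributes — and a register holds the superposition (cell-wise
union) of every function stored in it, i.e. a relation.

Three logical operations act on the table:

* **register** — cell-wise inclusive disjunction of the cue onto the
  table (the memory write),
* **recognize** — cell-wise material implication cue → table: true iff
  every cell the cue marks is already marked (direct rejection, no
  search),
* **retrieve** — constructive read: if the cue is recognized, each
  attribute's value is sampled from the contiguous run of marked cells
  around the cue using a discrete triangular distribution with the cue
  as mode.

The indeterminacy of the stored relation is measured by the
*computational entropy*: the mean over columns of ``log2`` of the
number of marked cells, in bits.  A register with entropy ``e`` holds
exactly ``2^(e*n)`` functions under strict recognition, out of a
maximum capacity of ``m^n``.

All external indices (attribute positions and values) are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AMRGrid",
    "RetrievalOutcome",
    "EmptyColumnError",
    "as_function",
    "register",
    "recognize",
    "retrieve",
    "entropy",
    "stored_count",
    "capacity",
    "mean_column_support",
    "sample_triangular",
    "triangular_weights",
]


class EmptyColumnError(ValueError):
    """Raised when a value run is requested from a column with no marks."""


@dataclass(frozen=True)
class RetrievalOutcome:
    """Result of a retrieval attempt.

    Attributes
    ----------
    accepted : bool
        Whether the cue passed recognition (possibly relaxed).
    function : numpy.ndarray or None
        The retrieved discrete function (1-based values); ``None``
        whenever ``accepted`` is False — retrieval is undefined for a
        rejected cue.
    failed_columns : frozenset of int
        1-based attribute indices where the cue's cell was off.
    """

    accepted: bool
    function: np.ndarray | None
    failed_columns: frozenset

    def __post_init__(self):
        if not self.accepted and self.function is not None:
            raise ValueError("a rejected retrieval carries no function")


def as_function(values: Sequence[int] | np.ndarray, n: int, m: int) -> np.ndarray:
    """Validate and coerce ``values`` to a discrete function on [1..m]^n.

    Returns an int64 array of shape ``(n,)``.  Raises ``ValueError`` on
    a length mismatch or any value outside ``[1, m]``.
    """
    f = np.asarray(values)
    if f.ndim != 1 or f.shape[0] != n:
        raise ValueError(f"expected a function of {n} arguments, got shape {f.shape}")
    if not np.issubdtype(f.dtype, np.integer):
        fi = np.asarray(f, dtype=np.int64)
        if not np.array_equal(fi, f):
            raise ValueError("function values must be integers")
        f = fi
    else:
        f = f.astype(np.int64, copy=False)
    if f.size and (f.min() < 1 or f.max() > m):
        raise ValueError(f"function values must lie in [1, {m}]")
    return f


def triangular_weights(v_l: int, v_u: int, mode: int) -> np.ndarray:
    """Closed-form weights of the discrete triangular law on [v_l, v_u].

    ``w(v) = 1 + span - |v - mode|`` with ``span = max(mode - v_l,
    v_u - mode)``, normalized.  Every point of the support gets strictly
    positive mass and the mode is the unique maximum.
    """
    if not (v_l <= mode <= v_u):
        raise ValueError(f"need v_l <= mode <= v_u, got ({v_l}, {mode}, {v_u})")
    span = max(mode - v_l, v_u - mode)
    v = np.arange(v_l, v_u + 1)
    w = (1 + span - np.abs(v - mode)).astype(float)
    return w / w.sum()


def sample_triangular(
    v_l: int, v_u: int, mode: int, rng: np.random.Generator
) -> int:
    """Draw one value from the discrete triangular law with the cue as mode."""
    if v_l == v_u:
        if mode != v_l:
            raise ValueError(f"need v_l <= mode <= v_u, got ({v_l}, {mode}, {v_u})")
        return int(v_l)
    w = triangular_weights(v_l, v_u, mode)
    return int(rng.choice(np.arange(v_l, v_u + 1), p=w))


class AMRGrid:
    """An n×m associative memory register.

    Parameters
    ----------
    n : int
        Number of attributes (columns of the conceptual table).
    m : int
        Number of discrete values each attribute may take (1-based).

    Notes
    -----
    ``cells[i, j]`` (0-based internally) is True iff value ``j+1`` is
    marked for attribute ``i+1``.  The table only ever gains marks:
    ``register`` is a cell-wise OR and nothing clears cells, so
    acceptance and entropy are monotone in the stored content.
    """

    def __init__(self, n: int, m: int):
        if n < 1 or m < 1:
            raise ValueError("n and m must be positive")
        self.n = int(n)
        self.m = int(m)
        self.cells = np.zeros((self.n, self.m), dtype=bool)
        self.registered_count = 0

    # ------------------------------------------------------------------
    # construction / copies
    @classmethod
    def from_cells(cls, cells: np.ndarray, registered_count: int = 0) -> "AMRGrid":
        cells = np.asarray(cells, dtype=bool)
        if cells.ndim != 2:
            raise ValueError("cells must be a 2-D boolean table")
        amr = cls(cells.shape[0], cells.shape[1])
        amr.cells = cells.copy()
        amr.registered_count = int(registered_count)
        return amr

    def copy(self) -> "AMRGrid":
        return AMRGrid.from_cells(self.cells, self.registered_count)

    # ------------------------------------------------------------------
    # the three memory operations
    def register(self, f: Sequence[int]) -> "AMRGrid":
        """Store a function: cell-wise OR of its grid onto the table."""
        f = as_function(f, self.n, self.m)
        self.cells[np.arange(self.n), f - 1] = True
        self.registered_count += 1
        return self

    def recognize(self, f: Sequence[int], k: int = 0) -> tuple[bool, frozenset]:
        """Test cue inclusion, tolerating up to ``k`` failing attributes.

        Returns ``(accepted, failed_columns)`` where ``failed_columns``
        holds the 1-based attribute indices whose cue cell is off.  With
        ``k = 0`` this is the strict material-implication test: accepted
        iff every cell the cue marks is marked in the table.
        """
        if not (0 <= k <= self.n):
            raise ValueError(f"relaxation k must lie in [0, {self.n}]")
        f = as_function(f, self.n, self.m)
        hit = self.cells[np.arange(self.n), f - 1]
        failed = frozenset((np.nonzero(~hit)[0] + 1).tolist())
        return len(failed) <= k, failed

    def recognize_batch(self, F: np.ndarray, k: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized recognition of many cues.

        ``F`` is a ``(T, n)`` integer array of cues.  Returns a boolean
        acceptance vector and the per-cue count of failing attributes.
        """
        F = np.asarray(F, dtype=np.int64)
        if F.ndim != 2 or F.shape[1] != self.n:
            raise ValueError(f"expected cues of shape (T, {self.n})")
        if F.size and (F.min() < 1 or F.max() > self.m):
            raise ValueError(f"cue values must lie in [1, {self.m}]")
        hit = self.cells[np.arange(self.n)[None, :], F - 1]
        n_failed = (~hit).sum(axis=1)
        return n_failed <= k, n_failed

    def retrieve(
        self,
        cue: Sequence[int],
        k: int = 0,
        rng: np.random.Generator | None = None,
    ) -> RetrievalOutcome:
        """Constructive read conditioned on (possibly relaxed) recognition.

        For an accepted cue, each attribute's value is drawn from the
        maximal contiguous run of marked cells around the cue with a
        triangular distribution whose mode is the cue's value — or, for
        an attribute that failed under relaxation, the marked cell
        nearest to the cue (ties toward the smaller value).  A column
        with no marks at all (only reachable when relaxation lets a
        partial relation through) echoes the cue's value.
        """
        if rng is None:
            rng = np.random.default_rng()
        accepted, failed = self.recognize(cue, k)
        if not accepted:
            return RetrievalOutcome(False, None, failed)
        cue = as_function(cue, self.n, self.m)
        out = np.empty(self.n, dtype=np.int64)
        for i in range(self.n):
            col = self.cells[i]
            if not col.any():
                out[i] = cue[i]  # partial relation: nothing to sample from
                continue
            v_l, v_u, mode = self._support_and_mode(i + 1, int(cue[i]))
            out[i] = sample_triangular(v_l, v_u, mode, rng)
        return RetrievalOutcome(True, out, failed)

    # ------------------------------------------------------------------
    # column structure
    def column_counts(self) -> np.ndarray:
        """Number of marked cells per attribute (the per-column counts)."""
        return self.cells.sum(axis=1)

    def column_support(self, i: int, cue_value: int) -> tuple[int, int]:
        """Maximal contiguous run of marked cells around a cue value.

        ``i`` and ``cue_value`` are 1-based.  If the cue's own cell is
        off, the run containing the nearest marked cell is returned
        (distance ties resolved toward the smaller value).  Raises
        :class:`EmptyColumnError` on a column with no marks.
        """
        v_l, v_u, _ = self._support_and_mode(i, cue_value)
        return v_l, v_u

    def _support_and_mode(self, i: int, cue_value: int) -> tuple[int, int, int]:
        if not (1 <= i <= self.n):
            raise ValueError(f"attribute index must lie in [1, {self.n}]")
        if not (1 <= cue_value <= self.m):
            raise ValueError(f"cue value must lie in [1, {self.m}]")
        col = self.cells[i - 1]
        on = np.nonzero(col)[0]  # 0-based
        if on.size == 0:
            raise EmptyColumnError(f"attribute {i} has no marked values")
        c = cue_value - 1
        if col[c]:
            anchor = c
        else:
            dist = np.abs(on - c)
            anchor = int(on[np.argmin(dist)])  # argmin ties -> smaller index
        lo = anchor
        while lo > 0 and col[lo - 1]:
            lo -= 1
        hi = anchor
        while hi < self.m - 1 and col[hi + 1]:
            hi += 1
        return lo + 1, hi + 1, anchor + 1

    # ------------------------------------------------------------------
    # entropy and capacity
    def entropy(self) -> float:
        """Computational entropy in bits: mean over columns of log2(count).

        Columns with zero or one mark contribute 0 — a column with no
        value assigned is fully determined by convention, and a single
        mark carries no indeterminacy.  Bounded by ``log2(m)``.
        """
        mu = self.column_counts()
        return float(np.log2(np.maximum(mu, 1)).sum() / self.n)

    def stored_count(self) -> float:
        """Number of functions held under strict recognition: 2^(e·n).

        Equals the product over columns of the marked-cell counts
        (empty columns counting as 1), which includes both explicitly
        registered functions and the collateral functions produced by
        superposition.  A fully empty register holds nothing and
        returns 0.
        """
        mu = self.column_counts()
        if not mu.any():
            return 0.0
        return float(np.prod(np.maximum(mu, 1), dtype=float))

    @property
    def capacity(self) -> int:
        """Maximum number of storable functions, ``m ** n``."""
        return self.m**self.n

    @property
    def n_cells(self) -> int:
        """Physical size of the table in bits (cells)."""
        return self.n * self.m

    # ------------------------------------------------------------------
    # persistence
    def to_json(self) -> str:
        doc = {
            "n": self.n,
            "m": self.m,
            "registered_count": self.registered_count,
            "cells": ["".join("1" if x else "0" for x in row) for row in self.cells],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "AMRGrid":
        doc = json.loads(text)
        n, m = int(doc["n"]), int(doc["m"])
        rows = doc["cells"]
        if len(rows) != n or any(len(r) != m for r in rows):
            raise ValueError("cell table does not match declared dimensions")
        cells = np.array([[ch == "1" for ch in row] for row in rows], dtype=bool)
        amr = cls.from_cells(cells, int(doc.get("registered_count", 0)))
        return amr

    def __eq__(self, other) -> bool:
        if not isinstance(other, AMRGrid):
            return NotImplemented
        return (
            self.n == other.n
            and self.m == other.m
            and self.registered_count == other.registered_count
            and bool(np.array_equal(self.cells, other.cells))
        )

    def __repr__(self) -> str:
        return (
            f"AMRGrid(n={self.n}, m={self.m}, "
            f"registered={self.registered_count}, entropy={self.entropy():.3f})"
        )


# ----------------------------------------------------------------------
# thin functional wrappers (non-mutating)

def register(amr: AMRGrid, f: Sequence[int]) -> AMRGrid:
    """Return a new register with ``f`` stored; ``amr`` is unchanged."""
    return amr.copy().register(f)


def recognize(amr: AMRGrid, f: Sequence[int], k: int = 0) -> tuple[bool, frozenset]:
    return amr.recognize(f, k)


def retrieve(
    amr: AMRGrid,
    cue: Sequence[int],
    k: int = 0,
    rng: np.random.Generator | None = None,
) -> RetrievalOutcome:
    return amr.retrieve(cue, k, rng)


def entropy(amr: AMRGrid) -> float:
    return amr.entropy()


def stored_count(amr: AMRGrid) -> float:
    return amr.stored_count()


def capacity(n: int, m: int) -> int:
    """Maximum number of functions an n×m register can hold: ``m ** n``."""
    return int(m) ** int(n)


def mean_column_support(e: float) -> float:
    """Geometric-mean marked cells per column of a register at entropy ``e``.

    Inverts the entropy definition: ``2 ** e``.  At e = 4.5 this is
    about 22.62 values per column.
    """
    return float(2.0**e)
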