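"""Register/recognize/retrieve semantics, entropy, and capacity arithmetic."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from entromem import (
    AMRGrid,
    EmptyColumnError,
    capacity,
    mean_column_support,
    sample_triangular,
    triangular_weights,
)
from entromem.core import register as reg_fn

from conftest import COLLATERALS, F1, F2, random_nonempty_amr


def enumerate_stored(amr: AMRGrid) -> int:
    """Independent oracle: count functions accepted by strict inclusion.

    Checks raw cell membership for every one of the m^n candidate
    functions, without going through the recognition code path.
    """
    count = 0
    for values in itertools.product(range(amr.m), repeat=amr.n):
        if all(amr.cells[i, v] for i, v in enumerate(values)):
            count += 1
    return count


# ----------------------------------------------------------------------
# registration

class TestRegister:
    def test_single_function_marks_exactly_its_cells(self):
        amr = AMRGrid(4, 7).register(F1)
        expected = np.zeros((4, 7), dtype=bool)
        for i, v in enumerate(F1):
            expected[i, v - 1] = True
        assert np.array_equal(amr.cells, expected)

    def test_union_of_two_functions_column_counts(self, two_function_amr):
        assert two_function_amr.column_counts().tolist() == [2, 1, 2, 1]

    def test_registering_twice_is_idempotent_on_cells(self):
        once = AMRGrid(4, 7).register(F1)
        twice = AMRGrid(4, 7).register(F1).register(F1)
        assert np.array_equal(once.cells, twice.cells)
        assert twice.registered_count == 2  # bookkeeping still counts calls

    @pytest.mark.parametrize("bad", [(1, 2, 4), (1, 2, 4, 8), (0, 2, 4, 7)])
    def test_dimension_or_range_mismatch_rejected(self, bad):
        with pytest.raises(ValueError):
            AMRGrid(4, 7).register(bad)

    def test_functional_wrapper_does_not_mutate(self):
        amr = AMRGrid(4, 7)
        out = reg_fn(amr, F1)
        assert not amr.cells.any()
        assert out.cells.any()


# ----------------------------------------------------------------------
# recognition

class TestRecognize:
    def test_stored_and_collateral_functions_accepted(self, two_function_amr):
        for f in (F1, F2, *COLLATERALS):
            accepted, failed = two_function_amr.recognize(f)
            assert accepted and not failed

    def test_empty_register_rejects_everything(self):
        amr = AMRGrid(4, 7)
        accepted, failed = amr.recognize(F1)
        assert not accepted
        assert failed == frozenset({1, 2, 3, 4})

    def test_relaxation_admits_single_failing_attribute(self, two_function_amr):
        cue = (1, 1, 4, 7)  # attribute 2 points at an unmarked value
        accepted, failed = two_function_amr.recognize(cue, k=0)
        assert not accepted and failed == frozenset({2})
        accepted, _ = two_function_amr.recognize(cue, k=1)
        assert accepted

    def test_batch_matches_scalar_recognition(self, two_function_amr):
        rng = np.random.default_rng(5)
        cues = rng.integers(1, 8, size=(40, 4))
        acc, nf = two_function_amr.recognize_batch(cues)
        for row, a, f in zip(cues, acc, nf):
            sa, sf = two_function_amr.recognize(row)
            assert sa == a and len(sf) == f


# ----------------------------------------------------------------------
# column support and triangular sampling

class TestColumnSupport:
    def _column(self, on, m=8):
        amr = AMRGrid(1, m)
        for j in on:
            amr.cells[0, j - 1] = True
        return amr

    def test_contiguous_run_around_cue(self):
        assert self._column({3, 4, 5}).column_support(1, 4) == (3, 5)

    def test_singleton_run(self):
        assert self._column({5}).column_support(1, 5) == (5, 5)

    def test_run_stops_at_gap(self):
        assert self._column({1, 2, 6}).column_support(1, 2) == (1, 2)

    def test_off_cue_snaps_to_nearest_mark_tie_to_smaller(self):
        # marks at 2 and 6, cue 4: equidistant, smaller value wins
        assert self._column({2, 6}).column_support(1, 4) == (2, 2)

    def test_empty_column_raises(self):
        with pytest.raises(EmptyColumnError):
            self._column(set()).column_support(1, 3)


class TestTriangular:
    def test_degenerate_support_is_constant(self):
        rng = np.random.default_rng(0)
        assert all(sample_triangular(5, 5, 5, rng) == 5 for _ in range(20))

    def test_invalid_ordering_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_triangular(3, 5, 6, rng)

    @pytest.mark.parametrize("v_l,v_u,mode", [(3, 5, 4), (3, 5, 3), (1, 9, 7)])
    def test_draws_fit_closed_form_weights(self, v_l, v_u, mode):
        rng = np.random.default_rng(1000 * v_l + 100 * v_u + mode)
        draws = np.array(
            [sample_triangular(v_l, v_u, mode, rng) for _ in range(10_000)]
        )
        assert draws.min() >= v_l and draws.max() <= v_u
        values, counts = np.unique(draws, return_counts=True)
        full = np.zeros(v_u - v_l + 1)
        full[values - v_l] = counts
        expected = triangular_weights(v_l, v_u, mode) * len(draws)
        assert stats.chisquare(full, expected).pvalue > 0.01
        # empirical mode is the requested mode
        assert values[np.argmax(counts)] == mode


# ----------------------------------------------------------------------
# retrieval

class TestRetrieve:
    def test_single_function_register_returns_cue_exactly(self):
        amr = AMRGrid(4, 7).register(F1)
        for seed in range(5):
            out = amr.retrieve(F1, rng=np.random.default_rng(seed))
            assert out.accepted
            assert out.function.tolist() == list(F1)

    def test_rejected_cue_has_no_function(self):
        amr = AMRGrid(4, 7).register(F1)
        out = amr.retrieve((2, 2, 4, 7), rng=np.random.default_rng(0))
        assert not out.accepted and out.function is None

    def test_two_function_register_draws_only_stored_functions(
        self, two_function_amr
    ):
        stored = {F1, F2, *COLLATERALS}
        rng = np.random.default_rng(42)
        for _ in range(1000):
            out = two_function_amr.retrieve(F1, rng=rng)
            assert tuple(out.function.tolist()) in stored

    def test_retrieved_function_is_recognized_strictly(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            amr = random_nonempty_amr(rng)
            cue = rng.integers(1, amr.m + 1, size=amr.n)
            out = amr.retrieve(cue, k=amr.n, rng=rng)
            assert out.accepted
            assert amr.recognize(out.function)[0]

    def test_relaxed_column_echoes_cue_when_column_empty(self):
        amr = AMRGrid(2, 4)
        amr.cells[0, 1] = True  # column 2 left empty: partial relation
        out = amr.retrieve((2, 3), k=1, rng=np.random.default_rng(0))
        assert out.accepted
        assert out.function.tolist() == [2, 3]
        assert out.failed_columns == frozenset({2})


# ----------------------------------------------------------------------
# entropy / capacity

class TestEntropy:
    def test_single_function_has_zero_entropy(self):
        assert AMRGrid(4, 7).register(F1).entropy() == 0.0

    def test_two_function_register_entropy_is_half_bit(self, two_function_amr):
        assert two_function_amr.entropy() == pytest.approx(0.5)

    def test_saturated_grid_entropy_is_log2_m(self):
        amr = AMRGrid(3, 8)
        amr.cells[:] = True
        assert amr.entropy() == pytest.approx(3.0)

    def test_empty_register_has_zero_entropy_and_zero_stored(self):
        amr = AMRGrid(4, 7)
        assert amr.entropy() == 0.0
        assert amr.stored_count() == 0.0

    def test_two_function_register_stores_four_of_2401(self, two_function_amr):
        assert two_function_amr.stored_count() == 4.0
        assert two_function_amr.capacity == 2401
        assert capacity(4, 7) == 2401

    def test_stored_count_matches_exhaustive_enumeration(self, two_function_amr):
        assert enumerate_stored(two_function_amr) == 4

    def test_mean_column_support_inverts_entropy(self):
        assert mean_column_support(0.0) == 1.0
        assert mean_column_support(4.5) == pytest.approx(2**4.5)

    def test_table_bit_count(self):
        assert AMRGrid(64, 64).n_cells == 4096


# ----------------------------------------------------------------------
# persistence

class TestPersistence:
    def test_json_round_trip_is_bit_exact(self, two_function_amr):
        text = two_function_amr.to_json()
        doc = json.loads(text)
        assert doc["n"] == 4 and doc["m"] == 7
        assert all(set(row) <= {"0", "1"} and len(row) == 7 for row in doc["cells"])
        back = AMRGrid.from_json(text)
        assert back == two_function_amr

    def test_dimension_mismatch_in_document_rejected(self):
        with pytest.raises(ValueError):
            AMRGrid.from_json('{"n": 2, "m": 3, "cells": ["000"]}')


# ----------------------------------------------------------------------
# invariants (property-based, derandomised)

sizes = st.tuples(st.integers(1, 6), st.integers(1, 6))


@st.composite
def amr_and_functions(draw):
    n, m = draw(sizes)
    count = draw(st.integers(1, 4))
    fs = [
        draw(st.lists(st.integers(1, m), min_size=n, max_size=n))
        for _ in range(count)
    ]
    return n, m, fs


@settings(max_examples=60, derandomize=True)
@given(amr_and_functions())
def test_inclusion_after_registration(case):
    n, m, fs = case
    amr = AMRGrid(n, m)
    for f in fs:
        amr.register(f)
        assert amr.recognize(f)[0]


@settings(max_examples=60, derandomize=True)
@given(amr_and_functions(), st.integers(0, 3))
def test_acceptance_monotone_under_registration(case, k):
    n, m, fs = case
    amr = AMRGrid(n, m)
    cue = fs[0]
    k = min(k, n)
    for f in fs:
        before = amr.recognize(cue, k)[0]
        amr.register(f)
        after = amr.recognize(cue, k)[0]
        assert after or not before  # storing only adds marks


@settings(max_examples=60, derandomize=True)
@given(amr_and_functions())
def test_entropy_monotone_and_bounded(case):
    n, m, fs = case
    amr = AMRGrid(n, m)
    prev = amr.entropy()
    for f in fs:
        amr.register(f)
        e = amr.entropy()
        assert e >= prev - 1e-12
        assert 0.0 <= e <= np.log2(m) + 1e-12
        prev = e


@settings(max_examples=40, derandomize=True)
@given(amr_and_functions())
def test_capacity_identity_against_enumeration(case):
    n, m, fs = case
    amr = AMRGrid(n, m)
    for f in fs:
        amr.register(f)
    product = float(np.prod(np.maximum(amr.column_counts(), 1), dtype=float))
    assert amr.stored_count() == product
    assert 2 ** (amr.entropy() * n) == pytest.approx(product)
    assert enumerate_stored(amr) == int(product)
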