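"""Extent analysis: synthetic extents, possibility degrees, weight vectors.

Frozen expected values for the worked two-item matrix were computed with the
independent brute-force oracle in ``oracles.py`` (float loops plus a
grid-search possibility degree), not with the implementation under test.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fuzzyahp import (
    PairwiseComparisonMatrix,
    TriangularFuzzyNumber as TFN,
    compute_weights,
    min_possibility,
    possibility_degree,
    synthetic_extents,
)
from conftest import random_valid_matrix
from oracles import brute_extent_weights, grid_possibility, random_tfn


def all_ones(n: int) -> PairwiseComparisonMatrix:
    return PairwiseComparisonMatrix.from_tfns(
        tuple(f"x{k}" for k in range(n)), [[TFN(1, 1, 1)] * n for _ in range(n)]
    )


# -- synthetic extents -------------------------------------------------------


@pytest.mark.parametrize("n", [2, 3])
def test_indifference_matrix_gives_equal_extents(n):
    extents = synthetic_extents(all_ones(n))
    for ext in extents.extents:
        assert ext.astuple() == pytest.approx((1 / n,) * 3)


def test_worked_matrix_extents(worked_2x2):
    """Row sums (2,4,6) and (1.2,1.33,2) against grand sum (3.2,5.33,8)."""
    extents = synthetic_extents(worked_2x2)
    assert extents[0].astuple() == pytest.approx((0.25, 0.7505, 1.875), abs=1e-4)
    assert extents[1].astuple() == pytest.approx((0.15, 0.2495, 0.625), abs=1e-4)


def test_extent_middles_sum_to_one(rng):
    for _ in range(40):
        n = int(rng.integers(2, 10))
        m = random_valid_matrix(rng, n)
        extents = synthetic_extents(m)
        assert sum(e.m for e in extents.extents) == pytest.approx(1.0, abs=1e-9)


# -- possibility degree ------------------------------------------------------


@pytest.mark.parametrize(
    "t1, t2, expected",
    [
        ((1, 2, 3), (1, 2, 3), 1.0),  # equal modes
        ((1, 2, 3), (4, 5, 6), 0.0),  # disjoint supports
        ((1, 2, 4), (3, 5, 7), 0.25),  # intersection height at x = 3.5
        ((1, 2, 3), (3, 4, 5), 0.0),  # touching supports, zero height
    ],
)
def test_possibility_degree_examples(t1, t2, expected):
    assert possibility_degree(TFN(*t1), TFN(*t2)) == pytest.approx(expected)


def test_possibility_degree_matches_grid_oracle(rng):
    for _ in range(150):
        t1, t2 = random_tfn(rng), random_tfn(rng)
        analytic = possibility_degree(TFN(*t1), TFN(*t2))
        assert analytic == pytest.approx(grid_possibility(t1, t2), abs=1e-4)


@given(
    st.tuples(*[st.floats(0.1, 20)] * 3).map(sorted),
    st.tuples(*[st.floats(0.1, 20)] * 3).map(sorted),
)
def test_one_direction_is_always_certain(a, b):
    """For any two TFNs, at least one of V(a>=b), V(b>=a) equals 1."""
    t1, t2 = TFN(*a), TFN(*b)
    assert max(possibility_degree(t1, t2), possibility_degree(t2, t1)) == 1.0


def test_possibility_degree_is_bounded(rng):
    for _ in range(200):
        v = possibility_degree(TFN(*random_tfn(rng)), TFN(*random_tfn(rng)))
        assert 0.0 <= v <= 1.0


# -- min-possibility and weights ---------------------------------------------


def test_min_possibility_of_equal_extents_is_one():
    extents = synthetic_extents(all_ones(2))
    assert min_possibility(0, extents) == 1.0
    assert min_possibility(1, extents) == 1.0


def test_min_possibility_worked_matrix(worked_2x2):
    """Dominant row is certain; the dominated row's degree is the
    intersection height (u2 - l1) / ((u2 - l1) + (m1 - m2)) = 0.4281."""
    extents = synthetic_extents(worked_2x2)
    assert min_possibility(0, extents) == 1.0
    assert min_possibility(1, extents) == pytest.approx(0.4281, abs=1e-4)


def test_min_possibility_index_out_of_range(worked_2x2):
    extents = synthetic_extents(worked_2x2)
    with pytest.raises(IndexError):
        min_possibility(5, extents)


@pytest.mark.parametrize("n", [2, 4, 7])
def test_indifference_matrix_gives_uniform_weights(n):
    w = compute_weights(all_ones(n))
    assert np.asarray(w.normalized) == pytest.approx(np.full(n, 1 / n))


def test_worked_matrix_weights_match_brute_force(worked_2x2):
    w = compute_weights(worked_2x2)
    grid = [[tuple(worked_2x2[i, j]) for j in range(2)] for i in range(2)]
    oracle = brute_extent_weights(grid)
    assert np.asarray(w.normalized) == pytest.approx(oracle, abs=1e-4)
    assert w.normalized == pytest.approx((0.7002, 0.2998), abs=1e-4)


def test_random_matrices_match_brute_force(rng):
    for n in (3, 5):
        m = random_valid_matrix(rng, n)
        w = compute_weights(m)
        grid = [[tuple(m[i, j]) for j in range(n)] for i in range(n)]
        assert np.asarray(w.normalized) == pytest.approx(
            brute_extent_weights(grid), abs=1e-4
        )


def test_crisp_dominance_yields_zero_weight():
    """Crisp judgments make extents with disjoint supports: the dominated
    item receives weight exactly 0 (the documented crisp-input degeneracy)."""
    m = PairwiseComparisonMatrix.from_upper_triangle(
        ("a", "b"), {(0, 1): TFN(5, 5, 5)}
    )
    w = compute_weights(m)
    assert w.normalized == pytest.approx((1.0, 0.0))


def test_weights_are_permutation_equivariant(rng):
    n = 5
    m = random_valid_matrix(rng, n)
    perm = rng.permutation(n)
    permuted = PairwiseComparisonMatrix(
        tuple(m.items[p] for p in perm), m.entries[np.ix_(perm, perm)]
    )
    w = np.asarray(compute_weights(m).normalized)
    w_perm = np.asarray(compute_weights(permuted).normalized)
    np.testing.assert_allclose(w_perm, w[perm], atol=1e-12)


def test_weights_sum_to_one_and_are_reproducible(rng):
    m = random_valid_matrix(rng, 6)
    w1 = compute_weights(m)
    w2 = compute_weights(m)
    assert sum(w1.normalized) == pytest.approx(1.0, abs=1e-9)
    assert w1.normalized == w2.normalized  # bit-for-bit
    assert all(0.0 <= x <= 1.0 for x in w1.nonnormal)
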