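"""Extent analysis: from one fuzzy pairwise matrix to a weight vector.

The procedure (Chang's extent-analysis scheme) has three steps:

1. **Synthetic extents.**  For row ``k`` of an ``n x n`` fuzzy judgment
   matrix, the synthetic extent is the fuzzy ratio of the row to the whole
   matrix::

       S_k = (sum_j M_kj) * (sum_i sum_j M_ij)^-1

   computed with componentwise TFN arithmetic.  An algebraic consequence is
   that the modal (middle) components of the ``S_k`` sum to exactly 1.

2. **Possibility degrees.**  The degree to which one TFN is at least as
   large as another is ``V(M1 >= M2) = 1`` when ``m1 >= m2``, 0 when the
   supports are disjoint (``u1 <= l2``), and otherwise the height of the
   intersection of the two membership functions,

       (u1 - l2) / ((u1 - l2) + (m2 - m1)),

   which lies strictly in (0, 1).

3. **Min-aggregation.**  The non-normal weight of item ``i`` is the minimum
   of ``V(S_i >= S_k)`` over all rivals ``k != i``; dividing by the sum
   gives the normalized weight vector.

Extent analysis is known to assign *exactly zero* weight to items whose
extents are dominated with disjoint support — especially with crisp (or
nearly crisp) judgments.  When every item is so dominated (all-zero
non-normal vector), normalization is impossible and
:class:`DegenerateWeightsError` is raised rather than silently returning a
uniform vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import PairwiseComparisonMatrix, validate_matrix
from .tfn import TriangularFuzzyNumber as TFN


class DegenerateWeightsError(ValueError):
    """All non-normal weights are zero, so no normalized vector exists."""


@dataclass(frozen=True)
class SyntheticExtentVector:
    """Per-row synthetic extents of a fuzzy comparison matrix."""

    extents: tuple[TFN, ...]

    def __len__(self) -> int:
        return len(self.extents)

    def __getitem__(self, k: int) -> TFN:
        return self.extents[k]

    def as_array(self) -> np.ndarray:
        return np.array([list(t) for t in self.extents], dtype=float)


@dataclass(frozen=True)
class WeightVector:
    """Non-normal (min-possibility) and sum-normalized weights per item."""

    items: tuple[str, ...]
    nonnormal: tuple[float, ...]
    normalized: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.items,
                "w_nonnormal": self.nonnormal,
                "w_normalized": self.normalized,
            }
        )


def synthetic_extents(
    matrix: PairwiseComparisonMatrix, *, validated: bool = False
) -> SyntheticExtentVector:
    """Compute the synthetic extent ``S_k`` for each row of the matrix."""
    if not validated:
        validate_matrix(matrix)
    e = matrix.entries  # (n, n, 3)
    row_sums = e.sum(axis=1)  # (n, 3)
    grand = e.sum(axis=(0, 1))  # (3,)
    grand_inv = (1.0 / grand)[::-1]  # fuzzy inverse: (1/u, 1/m, 1/l)
    extents = row_sums * grand_inv  # componentwise product per row
    return SyntheticExtentVector(tuple(TFN(*row) for row in extents))


def possibility_degree(m1: TFN, m2: TFN) -> float:
    """Possibility ``V(m1 >= m2)`` that one TFN is at least as large as another.

    Returns 1 when the first mode dominates, 0 when the supports merely touch
    or are disjoint, and the intersection height otherwise.
    """
    if m1.m >= m2.m:
        return 1.0
    if m1.u <= m2.l:
        # supports disjoint (or touching: intersection height is zero)
        return 0.0
    return (m1.u - m2.l) / ((m1.u - m2.l) + (m2.m - m1.m))


def min_possibility(target_index: int, extents: SyntheticExtentVector) -> float:
    """Minimum possibility that extent ``target_index`` exceeds each rival."""
    n = len(extents)
    if not 0 <= target_index < n:
        raise IndexError(f"target_index {target_index} out of range for {n} extents")
    if n < 2:
        raise ValueError("min_possibility needs at least 2 extents")
    target = extents[target_index]
    return min(
        possibility_degree(target, extents[k]) for k in range(n) if k != target_index
    )


def compute_weights(
    matrix: PairwiseComparisonMatrix, *, validated: bool = False
) -> WeightVector:
    """Full extent analysis of one matrix: extents -> min-possibility -> W.

    Deterministic for a fixed input.  Raises :class:`DegenerateWeightsError`
    when every item receives non-normal weight zero.
    """
    if not validated:
        validate_matrix(matrix)
    extents = synthetic_extents(matrix, validated=True)
    nonnormal = np.array(
        [min_possibility(i, extents) for i in range(matrix.n)], dtype=float
    )
    total = nonnormal.sum()
    if total == 0.0:
        raise DegenerateWeightsError(
            "extent analysis assigned zero possibility to every item "
            "(mutually dominated extents with disjoint supports); "
            "no normalized weight vector exists for this matrix"
        )
    normalized = nonnormal / total
    return WeightVector(matrix.items, tuple(nonnormal), tuple(normalized))
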