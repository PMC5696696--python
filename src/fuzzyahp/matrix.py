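"""Fuzzy pairwise-comparison matrices: construction, validation, and I/O.

A pairwise-comparison matrix holds one triangular fuzzy judgment per ordered
item pair.  Valid matrices have the identity ``(1, 1, 1)`` on the diagonal
and are fuzzy-reciprocal: the (j, i) entry is the componentwise fuzzy
inverse of the (i, j) entry.  A per-component tolerance (default 0.01)
accommodates judgments entered from 2-decimal printed reciprocal values.

Entries are stored as an ``(n, n, 3)`` float array (last axis = l, m, u) so
that extent analysis and aggregation can be vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import json

import numpy as np
import pandas as pd

from .tfn import TriangularFuzzyNumber as TFN

#: Per-component tolerance for reciprocity and diagonal checks.  Chosen so
#: that matrices keyed in from the 2-decimal printed reciprocal scale values
#: still validate.
RECIPROCITY_TOL = 0.01


class MatrixValidationError(ValueError):
    """Raised when a pairwise matrix violates its structural invariants.

    ``violations`` lists every offending cell, not just the first one.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid pairwise comparison matrix:\n  " + "\n  ".join(self.violations)
        )


@dataclass(frozen=True)
class PairwiseComparisonMatrix:
    """An ``n x n`` grid of TFN judgments over an ordered item list."""

    items: tuple[str, ...]
    entries: np.ndarray = field(repr=False)  # shape (n, n, 3)

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        n = len(self.items)
        if entries.shape != (n, n, 3):
            raise ValueError(
                f"entries must have shape ({n}, {n}, 3) for {n} items, "
                f"got {entries.shape}"
            )
        object.__setattr__(self, "items", tuple(str(i) for i in self.items))
        entries = entries.copy()
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)

    # -- basic access -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.items)

    def __getitem__(self, ij: tuple[int, int]) -> TFN:
        i, j = ij
        return TFN(*self.entries[i, j])

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_tfns(
        cls, items: Sequence[str], grid: Sequence[Sequence[TFN]]
    ) -> "PairwiseComparisonMatrix":
        """Build from a full nested sequence of TFNs (row-major)."""
        arr = np.array([[list(cell) for cell in row] for row in grid], dtype=float)
        return cls(tuple(items), arr)

    @classmethod
    def from_upper_triangle(
        cls, items: Sequence[str], upper: dict[tuple[int, int], TFN]
    ) -> "PairwiseComparisonMatrix":
        """Build from judgments for i < j; fills the diagonal with (1,1,1)
        and the lower triangle with exact analytic fuzzy reciprocals."""
        n = len(items)
        arr = np.empty((n, n, 3), dtype=float)
        arr[np.arange(n), np.arange(n)] = 1.0
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    t = upper[(i, j)]
                except KeyError:
                    raise KeyError(f"missing judgment for item pair ({i}, {j})") from None
                arr[i, j] = tuple(t)
                arr[j, i] = tuple(t.inverse())
        return cls(tuple(items), arr)

    def identity_like(self) -> "PairwiseComparisonMatrix":
        """An all-(1,1,1) matrix over the same items (total indifference)."""
        return type(self).from_tfns(
            self.items, [[TFN(1, 1, 1)] * self.n for _ in range(self.n)]
        )


def matrix_violations(
    matrix: PairwiseComparisonMatrix, tol: float = RECIPROCITY_TOL
) -> list[str]:
    """Return a description of every invariant violation (empty if valid)."""
    violations: list[str] = []
    e = matrix.entries
    n = matrix.n
    if n < 2:
        violations.append(f"matrix must compare at least 2 items, got n={n}")
        return violations
    ordered = (e[..., 0] <= e[..., 1] + 1e-12) & (e[..., 1] <= e[..., 2] + 1e-12)
    for i, j in zip(*np.nonzero(~ordered)):
        violations.append(
            f"cell ({matrix.items[i]}, {matrix.items[j]}): components not ordered "
            f"l <= m <= u: {tuple(e[i, j])}"
        )
    if np.any(e[..., 0] <= 0):
        for i, j in zip(*np.nonzero(e[..., 0] <= 0)):
            violations.append(
                f"cell ({matrix.items[i]}, {matrix.items[j]}): non-positive support "
                f"{tuple(e[i, j])}"
            )
        return violations  # reciprocity checks below would divide by zero
    diag = e[np.arange(n), np.arange(n)]
    bad_diag = np.any(np.abs(diag - 1.0) > tol, axis=-1)
    for i in np.nonzero(bad_diag)[0]:
        violations.append(
            f"diagonal cell ({matrix.items[i]}, {matrix.items[i]}) must be (1, 1, 1), "
            f"got {tuple(diag[i])}"
        )
    # reciprocity: entries[j, i] == (1/u, 1/m, 1/l) of entries[i, j]
    expected = 1.0 / e[..., ::-1]
    mismatch = np.abs(np.swapaxes(e, 0, 1) - expected).max(axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            if mismatch[i, j] > tol:
                violations.append(
                    f"reciprocity violated for ({matrix.items[i]}, {matrix.items[j]}): "
                    f"entry ({matrix.items[j]}, {matrix.items[i]}) = {tuple(e[j, i])}, "
                    f"expected inverse {tuple(expected[i, j])}"
                )
    return violations


def validate_matrix(
    matrix: PairwiseComparisonMatrix, tol: float = RECIPROCITY_TOL
) -> PairwiseComparisonMatrix:
    """Return the matrix unchanged if valid; raise :class:`MatrixValidationError`
    listing every violating cell otherwise."""
    violations = matrix_violations(matrix, tol=tol)
    if violations:
        raise MatrixValidationError(violations)
    return matrix


# -- I/O ---------------------------------------------------------------------


def matrix_to_long(matrix: PairwiseComparisonMatrix) -> pd.DataFrame:
    """Long-format frame with columns item_i, item_j, l, m, u (all cells)."""
    rows = []
    for i, a in enumerate(matrix.items):
        for j, b in enumerate(matrix.items):
            l, m, u = matrix.entries[i, j]
            rows.append({"item_i": a, "item_j": b, "l": l, "m": m, "u": u})
    return pd.DataFrame(rows)


def matrix_from_long(df: pd.DataFrame) -> PairwiseComparisonMatrix:
    """Rebuild a matrix from the long format written by :func:`matrix_to_long`.

    Item order follows first appearance in ``item_i``.  Missing cells raise.
    """
    required = {"item_i", "item_j", "l", "m", "u"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long-format matrix is missing columns: {sorted(missing)}")
    items = list(dict.fromkeys(df["item_i"].astype(str)))
    index = {it: k for k, it in enumerate(items)}
    n = len(items)
    arr = np.full((n, n, 3), np.nan)
    for rec in df.itertuples(index=False):
        i, j = index[str(rec.item_i)], index.get(str(rec.item_j))
        if j is None:
            raise ValueError(f"item {rec.item_j!r} appears only as item_j")
        arr[i, j] = (rec.l, rec.m, rec.u)
    if np.isnan(arr).any():
        holes = [
            f"({items[i]}, {items[j]})"
            for i, j in zip(*np.nonzero(np.isnan(arr[..., 0])))
        ]
        raise ValueError(f"long-format matrix has missing cells: {', '.join(holes)}")
    return PairwiseComparisonMatrix(tuple(items), arr)


def write_matrix(matrix: PairwiseComparisonMatrix, path: Union[str, Path]) -> None:
    """Write a matrix as long-format TSV, or as a JSON grid for ``.json``."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "items": list(matrix.items),
            "entries": [
                [list(matrix.entries[i, j]) for j in range(matrix.n)]
                for i in range(matrix.n)
            ],
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        matrix_to_long(matrix).to_csv(path, sep="\t", index=False)


def read_matrix(path: Union[str, Path]) -> PairwiseComparisonMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        return PairwiseComparisonMatrix(
            tuple(doc["items"]), np.asarray(doc["entries"], dtype=float)
        )
    return matrix_from_long(pd.read_csv(path, sep="\t"))
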