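"""Triangular fuzzy numbers and their componentwise arithmetic.

A triangular fuzzy number (TFN) ``(l, m, u)`` models an uncertain judgment
intensity: membership rises linearly from the lower support bound ``l`` to 1
at the mode ``m`` and falls linearly to 0 at the upper bound ``u``.  The
arithmetic used throughout the package is the standard componentwise
triangular approximation:

* addition: ``(l1+l2, m1+m2, u1+u2)``
* multiplication: ``(l1*l2, m1*m2, u1*u2)`` (positive operands)
* inverse: ``(1/u, 1/m, 1/l)`` (positive operands)

Multiplication and inversion are exact only at the mode; the support bounds
are the usual triangular approximation of the true fuzzy product.  No
rounding ever happens inside arithmetic; :func:`round_half_up` exists solely
for comparing against values printed at fixed decimal precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterator


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up (0.005 -> 0.01) to ``ndigits`` decimals.

    Python's built-in ``round`` is banker's rounding; printed decision-analysis
    tables conventionally round half-up, so comparisons against printed
    values go through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """An ordered triple ``l <= m <= u`` of support bounds and mode."""

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        if not (self.l <= self.m <= self.u):
            raise ValueError(
                f"TFN components must satisfy l <= m <= u, got "
                f"({self.l}, {self.m}, {self.u})"
            )

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return tfn_add(self, other)

    def __mul__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return tfn_mul(self, other)

    def inverse(self) -> "TriangularFuzzyNumber":
        return tfn_inv(self)

    # -- conveniences -------------------------------------------------------

    @property
    def is_positive(self) -> bool:
        return self.l > 0

    def membership(self, x: float) -> float:
        """Degree to which ``x`` belongs to this fuzzy number, in [0, 1]."""
        if x < self.l or x > self.u:
            return 0.0
        if x == self.m:
            return 1.0
        if x < self.m:
            return (x - self.l) / (self.m - self.l)
        return (self.u - x) / (self.u - self.m)

    def rounded(self, ndigits: int = 2) -> "TriangularFuzzyNumber":
        """Componentwise half-up rounding, for display against printed tables."""
        return TriangularFuzzyNumber(
            round_half_up(self.l, ndigits),
            round_half_up(self.m, ndigits),
            round_half_up(self.u, ndigits),
        )

    def astuple(self) -> tuple[float, float, float]:
        return (self.l, self.m, self.u)

    def __iter__(self) -> Iterator[float]:
        return iter(self.astuple())

    def isclose(self, other: "TriangularFuzzyNumber", tol: float = 1e-9) -> bool:
        return all(abs(a - b) <= tol for a, b in zip(self, other))


TFN = TriangularFuzzyNumber


def tfn_add(a: TriangularFuzzyNumber, b: TriangularFuzzyNumber) -> TriangularFuzzyNumber:
    """Componentwise sum of two TFNs."""
    return TriangularFuzzyNumber(a.l + b.l, a.m + b.m, a.u + b.u)


def tfn_mul(a: TriangularFuzzyNumber, b: TriangularFuzzyNumber) -> TriangularFuzzyNumber:
    """Componentwise product of two positive TFNs (triangular approximation)."""
    if not (a.is_positive and b.is_positive):
        raise ValueError("TFN multiplication requires strictly positive operands")
    return TriangularFuzzyNumber(a.l * b.l, a.m * b.m, a.u * b.u)


def tfn_inv(a: TriangularFuzzyNumber) -> TriangularFuzzyNumber:
    """Fuzzy reciprocal ``(1/u, 1/m, 1/l)`` of a positive TFN."""
    if not a.is_positive:
        raise ValueError("TFN inverse requires a strictly positive TFN")
    return TriangularFuzzyNumber(1.0 / a.u, 1.0 / a.m, 1.0 / a.l)
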