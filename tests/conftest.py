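from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fuzzyahp import PairwiseComparisonMatrix, TriangularFuzzyNumber as TFN

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def worked_2x2() -> PairwiseComparisonMatrix:
    """Two items, one 'moderately more important' judgment (plus reciprocal)."""
    return PairwiseComparisonMatrix.from_tfns(
        ("a", "b"),
        [[TFN(1, 1, 1), TFN(1, 3, 5)], [TFN(0.2, 0.33, 1), TFN(1, 1, 1)]],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def random_valid_matrix(
    rng: np.random.Generator, n: int, items: tuple[str, ...] | None = None
) -> PairwiseComparisonMatrix:
    """A random reciprocal matrix whose upper cells are uniform ladder rungs."""
    from fuzzyahp import scale_lookup

    if items is None:
        items = tuple(f"x{k}" for k in range(n))
    upper = {}
    for i in range(n):
        for j in range(i + 1, n):
            intensity = int(rng.integers(1, 10))
            fwd = scale_lookup(intensity).forward
            upper[(i, j)] = fwd if rng.random() < 0.5 else fwd.inverse()
    return PairwiseComparisonMatrix.from_upper_triangle(items, upper)
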