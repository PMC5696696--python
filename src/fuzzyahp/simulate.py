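"""Synthetic expert panels with known ground truth.

The study design this emulates: a panel of experts (22 by default) each
fills in fuzzy pairwise-comparison questionnaires over the criteria of a
node.  The generator works backwards from a known *true* weight vector:

1. ``sample_true_weights`` draws a positive normalized vector from a
   symmetric Dirichlet distribution.  One concentration knob spans
   near-uniform (large values) to highly skewed (small values) truths.  The
   default concentration of 3 gives, at 8 items, best-to-worst weight
   ratios typically in the 4-15 range — the spread published factor-weight
   tables in this domain actually show — while keeping most ideal
   judgments on the ladder rather than clipped at the extreme rung.
2. ``ideal_judgment`` converts each true ratio ``w_i / w_j`` to the nearest
   integer rung of the nine-level linguistic ladder (clipped to [1, 9]);
   ratios below one encode as the reciprocal orientation of the inverse
   intensity.
3. A noise model perturbs the *ordinal* rung, not the TFN components: each
   of ``max_steps`` trials moves the judgment one rung up or down the
   ladder with probability ``step_probability``.  The ladder is signed —
   stepping below "equally important" crosses into reciprocal territory —
   and clipped at the extreme rungs, so every perturbed judgment is still a
   legal scale entry and every generated matrix is valid by construction.

Judgment noise therefore emulates questionnaire behaviour (an expert picks
an adjacent verbal grade), not measurement error on fuzzy bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .aggregate import ExpertJudgmentSet
from .matrix import PairwiseComparisonMatrix
from .scale import MAX_INTENSITY, scale_lookup
from .tables import fixtures  # noqa: F401  (re-export: printed-table fixtures)
from .tfn import TriangularFuzzyNumber as TFN

#: Default symmetric-Dirichlet concentration for true weight vectors.
DEFAULT_CONCENTRATION = 3.0

#: Default panel size, matching the study design this package emulates.
DEFAULT_N_EXPERTS = 22


@dataclass(frozen=True)
class TrueWeightSpec:
    """A ground-truth weight vector and the sampler settings that drew it."""

    weights: tuple[float, ...]
    seed: Optional[int] = None
    concentration: float = DEFAULT_CONCENTRATION

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size < 2:
            raise ValueError("a weight vector needs at least 2 items")
        if np.any(w <= 0):
            raise ValueError("true weights must be strictly positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"true weights must sum to 1, got {w.sum()}")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @property
    def n_items(self) -> int:
        return len(self.weights)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


@dataclass(frozen=True)
class NoiseModel:
    """Ladder noise: ±1-rung steps on the signed ordinal judgment scale."""

    step_probability: float = 0.0
    max_steps: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.step_probability <= 1.0:
            raise ValueError("step_probability must lie in [0, 1]")
        if self.max_steps < 0:
            raise ValueError("max_steps must be >= 0")


@dataclass(frozen=True)
class SyntheticPanel:
    """Generated expert judgment sets plus the truth that generated them."""

    experts: tuple[ExpertJudgmentSet, ...]
    truth: dict[str, TrueWeightSpec] = field(hash=False)

    @property
    def n_experts(self) -> int:
        return len(self.experts)


def sample_true_weights(
    n: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
    concentration: float = DEFAULT_CONCENTRATION,
) -> TrueWeightSpec:
    """Draw a positive normalized truth vector from Dirichlet(concentration)."""
    if n < 2:
        raise ValueError(f"need at least 2 items, got n={n}")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(n, float(concentration)))
    # Dirichlet draws are almost surely positive; guard against underflow.
    w = np.clip(w, 1e-12, None)
    w = w / w.sum()
    stored_seed = seed if isinstance(seed, int) else None
    return TrueWeightSpec(tuple(w), seed=stored_seed, concentration=concentration)


def ideal_judgment(w_i: float, w_j: float) -> int:
    """Signed ladder intensity best matching the true ratio ``w_i / w_j``.

    Returns ``+k`` (k in 1..9) when item i is preferred at intensity k, and
    ``-k`` when item j is preferred; a ratio of exactly 1 returns 1
    ("equally important").  The ratio is rounded half-up to the nearest
    integer rung and clipped at the extreme rung 9.
    """
    if w_i <= 0 or w_j <= 0:
        raise ValueError("weights must be strictly positive")
    ratio = w_i / w_j
    flipped = ratio < 1.0
    if flipped:
        ratio = 1.0 / ratio
    intensity = int(np.floor(ratio + 0.5))
    intensity = max(1, min(MAX_INTENSITY, intensity))
    if intensity == 1:
        return 1
    return -intensity if flipped else intensity


def _signed_to_rung(signed: int) -> int:
    """Map signed intensity (+k / -k) to a position on the signed ladder.

    The ladder runs -8..+8: 0 is "equally important", +k-1 is forward
    intensity k, negative positions are reciprocal intensities.
    """
    return signed - 1 if signed > 0 else signed + 1


def _rung_to_entry(rung: int) -> TFN:
    intensity = abs(rung) + 1
    fwd = scale_lookup(intensity).forward
    return fwd if rung >= 0 else fwd.inverse()


def ideal_matrix(
    truth: TrueWeightSpec, items: Optional[Sequence[str]] = None
) -> PairwiseComparisonMatrix:
    """The noise-free judgment matrix implied by a truth vector."""
    n = truth.n_items
    if items is None:
        items = [f"item{k + 1}" for k in range(n)]
    w = truth.as_array()
    upper = {
        (i, j): _rung_to_entry(_signed_to_rung(ideal_judgment(w[i], w[j])))
        for i in range(n)
        for j in range(i + 1, n)
    }
    return PairwiseComparisonMatrix.from_upper_triangle(items, upper)


def _perturb_rung(rung: int, noise: NoiseModel, rng: np.random.Generator) -> int:
    for _ in range(noise.max_steps):
        if rng.random() < noise.step_probability:
            rung += int(rng.integers(0, 2)) * 2 - 1  # ±1
            rung = max(-(MAX_INTENSITY - 1), min(MAX_INTENSITY - 1, rung))
    return rung


def generate_panel(
    truth: Union[TrueWeightSpec, dict[str, TrueWeightSpec]],
    noise: NoiseModel = NoiseModel(),
    n_experts: int = DEFAULT_N_EXPERTS,
    seed: Optional[Union[int, np.random.Generator]] = None,
    items: Optional[dict[str, Sequence[str]]] = None,
) -> SyntheticPanel:
    """Generate a reproducible panel of expert judgment sets.

    ``truth`` maps node codes to truth vectors (a bare spec is treated as
    the single node ``"goal"``).  Every expert judges every node: the ideal
    signed rung for each item pair is perturbed by the noise model,
    independently per expert and pair, and the reciprocal cell is filled
    analytically so each matrix is valid by construction.
    """
    if n_experts < 1:
        raise ValueError("panel needs at least one expert")
    if isinstance(truth, TrueWeightSpec):
        truth = {"goal": truth}
    rng = np.random.default_rng(seed)
    experts = []
    for e in range(n_experts):
        matrices: dict[str, PairwiseComparisonMatrix] = {}
        for node, spec in truth.items():
            n = spec.n_items
            node_items = (
                list(items[node]) if items and node in items
                else [f"item{k + 1}" for k in range(n)]
            )
            w = spec.as_array()
            upper: dict[tuple[int, int], TFN] = {}
            for i in range(n):
                for j in range(i + 1, n):
                    rung = _signed_to_rung(ideal_judgment(w[i], w[j]))
                    rung = _perturb_rung(rung, noise, rng)
                    upper[(i, j)] = _rung_to_entry(rung)
            matrices[node] = PairwiseComparisonMatrix.from_upper_triangle(
                node_items, upper
            )
        experts.append(ExpertJudgmentSet(f"expert{e + 1:02d}", matrices))
    return SyntheticPanel(tuple(experts), dict(truth))


def write_truth(truth: dict[str, TrueWeightSpec], path: Union[str, Path]) -> None:
    """Write truth vectors as TSV (node_code, item_index, weight) for
    recovery experiments."""
    rows = [
        {"node_code": node, "item_index": k + 1, "weight": w}
        for node, spec in truth.items()
        for k, w in enumerate(spec.weights)
    ]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)
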