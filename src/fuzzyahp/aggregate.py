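"""Combining several experts' fuzzy judgment matrices into one matrix per node.

The default rule is the componentwise geometric mean of the experts' TFN
entries.  Among the standard pooling rules it is the only one that preserves
fuzzy reciprocity exactly: the geometric mean of reciprocals is the
reciprocal of the geometric mean (with the l/u swap of the fuzzy inverse),
so an aggregated matrix of valid reciprocal matrices is again valid.  A
componentwise arithmetic mean is available for sensitivity analysis; note it
does *not* preserve reciprocity in general, so aggregated matrices under
that rule are repaired by recomputing the lower triangle from the upper.

Aggregation happens on judgments (before extent analysis), not on weights,
so the pooled panel feeds the same single-matrix procedure as an individual
expert would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd

from .matrix import PairwiseComparisonMatrix, matrix_violations
from .scale import SCALE, scale_lookup
from .tfn import TriangularFuzzyNumber as TFN

AggregationRule = Literal["geometric", "arithmetic"]


@dataclass(frozen=True)
class ExpertJudgmentSet:
    """One expert's pairwise matrices, keyed by hierarchy node code."""

    expert_id: str
    matrices: dict[str, PairwiseComparisonMatrix]

    def nodes(self) -> tuple[str, ...]:
        return tuple(self.matrices)


@dataclass(frozen=True)
class CompletenessReport:
    """Findings from screening a panel; empty lists mean a clean panel."""

    missing_nodes: tuple[str, ...] = ()  # "expert:node" pairs absent
    ordering_conflicts: tuple[str, ...] = ()
    matrix_findings: tuple[str, ...] = ()  # per-expert invariant violations

    @property
    def ok(self) -> bool:
        return not (self.missing_nodes or self.ordering_conflicts or self.matrix_findings)


def panel_completeness(judgments: Sequence[ExpertJudgmentSet]) -> CompletenessReport:
    """Screen a panel for coverage gaps, ordering conflicts, and invalid matrices.

    Report-only: never raises.  The reference node set and item orderings are
    taken from the union over experts (first expert defining a node wins).
    """
    all_nodes: dict[str, tuple[str, ...]] = {}
    for ex in judgments:
        for node, m in ex.matrices.items():
            all_nodes.setdefault(node, m.items)
    missing, conflicts, findings = [], [], []
    for ex in judgments:
        for node, ref_items in all_nodes.items():
            m = ex.matrices.get(node)
            if m is None:
                missing.append(f"{ex.expert_id}:{node}")
                continue
            if m.items != ref_items:
                conflicts.append(
                    f"{ex.expert_id}:{node}: items {m.items} != expected {ref_items}"
                )
            for v in matrix_violations(m):
                findings.append(f"{ex.expert_id}:{node}: {v}")
    return CompletenessReport(tuple(missing), tuple(conflicts), tuple(findings))


def _stack(judgments: Sequence[ExpertJudgmentSet], node: str) -> np.ndarray:
    if not judgments:
        raise ValueError("cannot aggregate an empty expert panel")
    mats = []
    ref_items = None
    for ex in judgments:
        m = ex.matrices.get(node)
        if m is None:
            raise KeyError(f"expert {ex.expert_id!r} has no matrix for node {node!r}")
        if ref_items is None:
            ref_items = m.items
        elif m.items != ref_items:
            raise ValueError(
                f"expert {ex.expert_id!r} orders items {m.items} for node {node!r}, "
                f"expected {ref_items}"
            )
        mats.append(m.entries)
    return np.stack(mats)  # (E, n, n, 3)


def aggregate_geometric(
    judgments: Sequence[ExpertJudgmentSet], node: str
) -> PairwiseComparisonMatrix:
    """Componentwise geometric mean of all experts' matrices for one node."""
    stack = _stack(judgments, node)
    agg = np.exp(np.log(stack).mean(axis=0))
    items = judgments[0].matrices[node].items
    return PairwiseComparisonMatrix(items, agg)


def aggregate_arithmetic(
    judgments: Sequence[ExpertJudgmentSet], node: str
) -> PairwiseComparisonMatrix:
    """Componentwise arithmetic mean; lower triangle recomputed as the fuzzy
    inverse of the upper so that the result remains a valid reciprocal matrix."""
    stack = _stack(judgments, node)
    agg = stack.mean(axis=0)
    n = agg.shape[0]
    for i in range(n):
        agg[i, i] = 1.0
        for j in range(i + 1, n):
            agg[j, i] = (1.0 / agg[i, j])[::-1]
    items = judgments[0].matrices[node].items
    return PairwiseComparisonMatrix(items, agg)


def aggregate_panel(
    judgments: Sequence[ExpertJudgmentSet],
    rule: AggregationRule = "geometric",
) -> dict[str, PairwiseComparisonMatrix]:
    """Aggregate every node covered by the panel under the chosen rule."""
    if rule not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    fn = aggregate_geometric if rule == "geometric" else aggregate_arithmetic
    nodes: list[str] = []
    for ex in judgments:
        for node in ex.matrices:
            if node not in nodes:
                nodes.append(node)
    return {node: fn(judgments, node) for node in nodes}


# -- long-format panel I/O ---------------------------------------------------

PANEL_COLUMNS = ("expert_id", "node_code", "item_i", "item_j", "label")


def _forward_label(entry: TFN, tol: float = 1e-6) -> tuple[str, bool]:
    """Match a matrix cell to a scale rung.

    Returns (label, flipped): ``flipped`` means the cell equals the rung's
    reciprocal, i.e. the *column* item was preferred to the row item.
    """
    for e in SCALE:
        if entry.isclose(e.forward, tol):
            return e.label, False
    for e in SCALE:
        if entry.isclose(e.forward.inverse(), tol) or entry.isclose(e.reciprocal, 0.005):
            return e.label, True
    raise ValueError(
        f"matrix entry {entry.astuple()} does not match any rung of the "
        f"nine-level scale; only scale-valued judgments can be written to "
        f"the long panel format"
    )


def panel_to_frame(judgments: Sequence[ExpertJudgmentSet]) -> pd.DataFrame:
    """Serialize a panel of scale-valued judgments to long format.

    Each unordered item pair appears once per expert and node, oriented so
    that ``item_i`` is the preferred item and ``label`` its forward grade.
    """
    rows = []
    for ex in judgments:
        for node, m in ex.matrices.items():
            for i in range(m.n):
                for j in range(i + 1, m.n):
                    label, flipped = _forward_label(m[i, j])
                    a, b = (m.items[j], m.items[i]) if flipped else (m.items[i], m.items[j])
                    rows.append(
                        {
                            "expert_id": ex.expert_id,
                            "node_code": node,
                            "item_i": a,
                            "item_j": b,
                            "label": label,
                        }
                    )
    return pd.DataFrame(rows, columns=list(PANEL_COLUMNS))


def frame_to_panel(
    df: pd.DataFrame, item_order: dict[str, Sequence[str]] | None = None
) -> list[ExpertJudgmentSet]:
    """Rebuild a panel from the long format.

    ``item_order`` optionally pins the item ordering per node; otherwise
    items are ordered by first appearance within each node (shared across
    experts so the panel is conformable).
    """
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel frame is missing columns: {sorted(missing)}")
    node_items: dict[str, list[str]] = {}
    if item_order:
        node_items = {node: list(items) for node, items in item_order.items()}
    else:
        for rec in df.itertuples(index=False):
            lst = node_items.setdefault(str(rec.node_code), [])
            for it in (str(rec.item_i), str(rec.item_j)):
                if it not in lst:
                    lst.append(it)
    experts: list[ExpertJudgmentSet] = []
    for expert_id, exdf in df.groupby("expert_id", sort=False):
        matrices: dict[str, PairwiseComparisonMatrix] = {}
        for node, ndf in exdf.groupby("node_code", sort=False):
            items = node_items[str(node)]
            index = {it: k for k, it in enumerate(items)}
            upper: dict[tuple[int, int], TFN] = {}
            for rec in ndf.itertuples(index=False):
                fwd = scale_lookup(str(rec.label)).forward
                i, j = index[str(rec.item_i)], index[str(rec.item_j)]
                if i < j:
                    upper[(i, j)] = fwd
                else:
                    upper[(j, i)] = fwd.inverse()
            matrices[str(node)] = PairwiseComparisonMatrix.from_upper_triangle(
                items, upper
            )
        experts.append(ExpertJudgmentSet(str(expert_id), matrices))
    return experts


def write_panel(judgments: Sequence[ExpertJudgmentSet], path: Union[str, Path]) -> None:
    panel_to_frame(judgments).to_csv(Path(path), sep="\t", index=False)


def read_panel(path: Union[str, Path]) -> list[ExpertJudgmentSet]:
    return frame_to_panel(pd.read_csv(Path(path), sep="\t"))
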