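"""Group aggregation: geometric-mean pooling and panel screening."""

import numpy as np
import pytest

from fuzzyahp import (
    ExpertJudgmentSet,
    PairwiseComparisonMatrix,
    TriangularFuzzyNumber as TFN,
    aggregate_arithmetic,
    aggregate_geometric,
    aggregate_panel,
    panel_completeness,
    read_panel,
    validate_matrix,
    write_panel,
)
from conftest import random_valid_matrix


def expert(eid: str, matrix: PairwiseComparisonMatrix, node: str = "goal"):
    return ExpertJudgmentSet(eid, {node: matrix})


def test_single_expert_aggregation_is_identity(worked_2x2):
    agg = aggregate_geometric([expert("e1", worked_2x2)], "goal")
    np.testing.assert_allclose(agg.entries, worked_2x2.entries)


def test_identical_experts_aggregate_to_the_common_matrix(worked_2x2):
    panel = [expert(f"e{k}", worked_2x2) for k in range(5)]
    agg = aggregate_geometric(panel, "goal")
    np.testing.assert_allclose(agg.entries, worked_2x2.entries, atol=1e-12)


def test_two_expert_geometric_mean_value():
    """Pooling 'moderately more important' with its reciprocal gives the
    componentwise square root of the product: (0.447, 0.995, 2.236)."""
    m1 = PairwiseComparisonMatrix.from_upper_triangle(("a", "b"), {(0, 1): TFN(1, 3, 5)})
    m2 = PairwiseComparisonMatrix.from_upper_triangle(
        ("a", "b"), {(0, 1): TFN(0.2, 0.33, 1)}
    )
    agg = aggregate_geometric([expert("e1", m1), expert("e2", m2)], "goal")
    assert agg[0, 1].astuple() == pytest.approx(
        (np.sqrt(0.2), np.sqrt(0.99), np.sqrt(5.0))
    )


def test_aggregation_preserves_reciprocity_exactly(rng):
    panel = [expert(f"e{k}", random_valid_matrix(rng, 6)) for k in range(8)]
    agg = aggregate_geometric(panel, "goal")
    e = agg.entries
    for i in range(6):
        for j in range(6):
            np.testing.assert_allclose(e[j, i], (1.0 / e[i, j])[::-1], atol=1e-12)
    validate_matrix(agg)


def test_aggregation_is_permutation_invariant_over_experts(rng):
    panel = [expert(f"e{k}", random_valid_matrix(rng, 4)) for k in range(6)]
    agg1 = aggregate_geometric(panel, "goal")
    agg2 = aggregate_geometric(panel[::-1], "goal")
    np.testing.assert_allclose(agg1.entries, agg2.entries, atol=1e-14)


def test_raising_one_judgment_never_lowers_the_aggregate():
    base = PairwiseComparisonMatrix.from_upper_triangle(("a", "b"), {(0, 1): TFN(1, 3, 5)})
    raised = PairwiseComparisonMatrix.from_upper_triangle(("a", "b"), {(0, 1): TFN(3, 5, 7)})
    other = PairwiseComparisonMatrix.from_upper_triangle(("a", "b"), {(0, 1): TFN(1, 2, 3)})
    low = aggregate_geometric([expert("e1", base), expert("e2", other)], "goal")
    high = aggregate_geometric([expert("e1", raised), expert("e2", other)], "goal")
    assert all(h >= l for h, l in zip(high[0, 1], low[0, 1]))


def test_arithmetic_rule_repairs_reciprocity(rng):
    panel = [expert(f"e{k}", random_valid_matrix(rng, 5)) for k in range(4)]
    agg = aggregate_panel(panel, rule="arithmetic")["goal"]
    validate_matrix(agg)


def test_empty_panel_rejected():
    with pytest.raises(ValueError, match="empty"):
        aggregate_geometric([], "goal")


def test_mismatched_item_sets_rejected(worked_2x2):
    other = PairwiseComparisonMatrix.from_upper_triangle(("x", "y"), {(0, 1): TFN(1, 2, 3)})
    with pytest.raises(ValueError, match="orders items"):
        aggregate_geometric([expert("e1", worked_2x2), expert("e2", other)], "goal")


# -- completeness screening --------------------------------------------------


def test_complete_panel_has_empty_report(worked_2x2):
    report = panel_completeness([expert(f"e{k}", worked_2x2) for k in range(3)])
    assert report.ok


def test_missing_node_is_named(worked_2x2):
    full = ExpertJudgmentSet("e1", {"goal": worked_2x2, "F3": worked_2x2})
    partial = ExpertJudgmentSet("e2", {"goal": worked_2x2})
    report = panel_completeness([full, partial])
    assert not report.ok
    assert "e2:F3" in report.missing_nodes


def test_transposed_but_not_inverted_entry_is_flagged():
    bad = PairwiseComparisonMatrix.from_tfns(
        ("a", "b"),
        [[TFN(1, 1, 1), TFN(1, 3, 5)], [TFN(1, 3, 5), TFN(1, 1, 1)]],
    )
    report = panel_completeness([expert("e1", bad)])
    assert any("reciprocity" in f for f in report.matrix_findings)


# -- long-format panel I/O ---------------------------------------------------


def test_panel_roundtrips_through_disk(tmp_path, rng):
    mats = {
        "goal": random_valid_matrix(rng, 4, items=("w", "x", "y", "z")),
        "F1": random_valid_matrix(rng, 3, items=("p", "q", "r")),
    }
    panel = [ExpertJudgmentSet(f"e{k}", mats) for k in range(3)]
    path = tmp_path / "panel.tsv"
    write_panel(panel, path)
    back = read_panel(path)
    assert [e.expert_id for e in back] == ["e0", "e1", "e2"]
    for orig, loaded in zip(panel, back):
        for node in mats:
            np.testing.assert_allclose(
                loaded.matrices[node].entries, orig.matrices[node].entries, atol=1e-12
            )
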