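"""Synthetic panels: truth sampling, ladder encoding, noise, and fixtures."""

import numpy as np
import pytest

from fuzzyahp import (
    NoiseModel,
    fixtures,
    generate_panel,
    ideal_judgment,
    ideal_matrix,
    matrix_to_long,
    sample_true_weights,
    scale_lookup,
    tfn_inv,
    validate_matrix,
)
from fuzzyahp.aggregate import panel_to_frame


# -- truth sampling ----------------------------------------------------------


def test_sampled_weights_are_positive_and_normalized():
    spec = sample_true_weights(4, seed=11)
    w = spec.as_array()
    assert (w > 0).all()
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_sampling_is_deterministic_for_fixed_seed():
    assert sample_true_weights(6, seed=3).weights == sample_true_weights(6, seed=3).weights


def test_single_item_truth_rejected():
    with pytest.raises(ValueError, match="at least 2"):
        sample_true_weights(1, seed=0)


def test_concentration_controls_spread():
    """Smaller concentration gives more skewed truths on average."""
    spread = lambda conc: np.mean(
        [
            (w := sample_true_weights(8, s, conc).as_array()).max() / w.min()
            for s in range(40)
        ]
    )
    assert spread(0.5) > spread(10.0)


# -- ladder encoding ---------------------------------------------------------


@pytest.mark.parametrize(
    "wi, wj, expected",
    [
        (0.3, 0.3, 1),  # equal weights: "equally important"
        (0.485, 0.05, 9),  # ratio 9.7 clips at the extreme rung
        (0.3, 0.1, 3),
        (0.1, 0.3, -3),  # preference flips to the reciprocal orientation
        (0.14, 0.1, 1),  # ratio 1.4 rounds down to indifference
    ],
)
def test_ideal_judgment_mapping(wi, wj, expected):
    assert ideal_judgment(wi, wj) == expected


def test_ideal_judgment_rejects_nonpositive():
    with pytest.raises(ValueError):
        ideal_judgment(0.0, 0.5)


def test_ratio_three_roundtrips_through_the_scale():
    """A true ratio of 3 produces the 'moderately more important' cell and
    the matching analytic reciprocal in the mirror cell."""
    spec = sample_true_weights(2, seed=5)
    w = np.array([0.75, 0.25])
    m = ideal_matrix(type(spec)(tuple(w)))
    fwd = scale_lookup(3).forward
    assert m[0, 1].astuple() == pytest.approx(fwd.astuple())
    assert m[1, 0].astuple() == pytest.approx(tfn_inv(fwd).astuple())


# -- panel generation --------------------------------------------------------


def test_zero_noise_experts_all_equal_the_ideal_matrix():
    truth = sample_true_weights(5, seed=2)
    panel = generate_panel(truth, NoiseModel(0.0), n_experts=4, seed=9)
    ideal = ideal_matrix(truth)
    for ex in panel.experts:
        np.testing.assert_allclose(ex.matrices["goal"].entries, ideal.entries)


def test_default_panel_has_22_experts():
    truth = sample_true_weights(3, seed=1)
    assert generate_panel(truth, seed=0).n_experts == 22


def test_generation_is_byte_identical_for_fixed_seed():
    truth = sample_true_weights(6, seed=8)
    noise = NoiseModel(0.4, max_steps=2)
    p1 = generate_panel(truth, noise, n_experts=5, seed=123)
    p2 = generate_panel(truth, noise, n_experts=5, seed=123)
    f1 = panel_to_frame(p1.experts).to_csv(index=False)
    f2 = panel_to_frame(p2.experts).to_csv(index=False)
    assert f1 == f2


def test_generated_matrices_are_always_valid(rng):
    for _ in range(10):
        truth = sample_true_weights(int(rng.integers(2, 9)), rng)
        panel = generate_panel(truth, NoiseModel(1.0, max_steps=3), n_experts=3, seed=rng)
        for ex in panel.experts:
            for m in ex.matrices.values():
                validate_matrix(m)
                # every cell is a legal ladder value or its reciprocal
                for _, row in matrix_to_long(m).iterrows():
                    assert row["l"] <= row["m"] <= row["u"]


def test_noise_parameters_validated():
    with pytest.raises(ValueError):
        NoiseModel(step_probability=1.5)
    with pytest.raises(ValueError):
        NoiseModel(step_probability=0.2, max_steps=-1)


def test_noise_moves_judgments_along_the_ladder():
    truth = sample_true_weights(6, seed=4)
    noisy = generate_panel(truth, NoiseModel(1.0, max_steps=2), n_experts=6, seed=77)
    ideal = ideal_matrix(truth)
    diffs = sum(
        not np.allclose(ex.matrices["goal"].entries, ideal.entries)
        for ex in noisy.experts
    )
    assert diffs > 0


# -- printed-table fixtures --------------------------------------------------


def test_factor_scores_sum_as_printed():
    assert fixtures().table2["score"].sum() == pytest.approx(0.999, abs=1e-12)


def test_top_law_subfactor_score():
    f7 = fixtures().table3["F7"].set_index("code")
    assert f7.loc["C44", "score"] == 0.444
    assert f7.loc["C44", "priority"] == 1


def test_numbering_gap_is_preserved():
    codes = [c for block in fixtures().table3.values() for c in block["code"]]
    assert "C31" not in codes
    assert len(codes) == 54
    assert len(set(codes)) == 54
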