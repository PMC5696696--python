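"""A full panel run: simulate 22 experts, aggregate, weigh, rank.

Generates a synthetic 22-expert panel over 8 criteria from a known true
weight vector with questionnaire noise (each judgment moves one rung on the
nine-level ladder with probability 0.2), pools the panel by componentwise
geometric mean, and runs extent analysis on the pooled matrix.  The final
table compares the recovered ranking with the truth that generated the
panel.
"""

import numpy as np
import pandas as pd

from fuzzyahp import (
    NoiseModel,
    aggregate_panel,
    compute_weights,
    generate_panel,
    panel_completeness,
    rank_dense,
    sample_true_weights,
)

truth = sample_true_weights(8, seed=20260921)
panel = generate_panel(truth, NoiseModel(step_probability=0.2), n_experts=22, seed=1)
print(f"panel: {panel.n_experts} experts, {truth.n_items} items, "
      f"screening ok = {panel_completeness(panel.experts).ok}")

pooled = aggregate_panel(panel.experts, rule="geometric")["goal"]
weights = compute_weights(pooled)

table = pd.DataFrame(
    {
        "item": weights.items,
        "true_weight": np.round(truth.weights, 3),
        "recovered": np.round(weights.normalized, 3),
        "true_rank": rank_dense(truth.weights).priorities,
        "recovered_rank": rank_dense(weights.normalized).priorities,
    }
)
print(table.to_string(index=False))
print("\nRanks agree where the ladder can see the difference; items whose")
print("true ratios round to the same rung may swap or tie.")
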