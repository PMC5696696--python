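# fuzzyahp

Fuzzy analytic-hierarchy-process (AHP) prioritization by extent analysis:
from multi-expert linguistic pairwise judgments over a goal → factor →
subfactor hierarchy to fuzzy weights and dense priority ranks.

The package targets health-systems and multi-criteria decision-analysis
work of the kind used to rank the factors affecting the development of
military hospital beds: a panel of experts compares criteria pairwise on a
nine-rung verbal ladder, each rung backed by a triangular fuzzy number
(TFN), and the analyst needs defensible weights and priorities out the
other end. Because studies of this kind rarely publish their raw
questionnaires, the package ships a synthetic expert-panel generator with
known ground truth so every step of the pipeline can be validated end to
end.

## The method

A TFN `M = (l, m, u)` has membership rising linearly from `l` to 1 at `m`
and falling to 0 at `u`. Judgment matrices are fuzzy-reciprocal:
`a_ji = (1/u_ij, 1/m_ij, 1/l_ij)`. For one matrix, extent analysis
computes per-row synthetic extents

    S_k = Σ_j M_kj ⊗ ( Σ_i Σ_j M_ij )⁻¹ ,

compares them with the possibility degree

    V(M₁ ≥ M₂) = 1                                if m₁ ≥ m₂
               = 0                                if u₁ ≤ l₂
               = (u₁ − l₂) / ((u₁ − l₂) + (m₂ − m₁))   otherwise,

takes non-normal weights `W′(i) = min_{k≠i} V(S_i ≥ S_k)`, and normalizes
by the sum. Panels are pooled before extent analysis with a componentwise
geometric mean (the rule that preserves fuzzy reciprocity). Scores are
ranked dense-descending: tied scores share a priority and the next distinct
score continues at the next integer. See `docs/methods.md` for assumptions,
conventions, and the method's known zero-weight pathology.

## Worked example

Two criteria, one judgment: "bed capacity" is *moderately more important*
than "staffing", i.e. the cell holds `(1, 3, 5)` and its mirror the fuzzy
reciprocal.

```python
from fuzzyahp import (PairwiseComparisonMatrix, TriangularFuzzyNumber as TFN,
                      compute_weights, synthetic_extents)

m = PairwiseComparisonMatrix.from_upper_triangle(
    ("bed capacity", "staffing"), {(0, 1): TFN(1, 3, 5)})
for item, ext in zip(m.items, synthetic_extents(m).extents):
    print(item, tuple(round(float(x), 4) for x in ext))
print(compute_weights(m).to_frame().round(4).to_string(index=False))
```

prints

```
bed capacity (0.25, 0.75, 1.875)
staffing (0.15, 0.25, 0.625)
        item  w_nonnormal  w_normalized
bed capacity       1.0000           0.7
    staffing       0.4286           0.3
```

Row sums `(2, 4, 6)` and `(1.2, 1.33, 2)` divided fuzzily by the grand sum
`(3.2, 5.33, 8)` give the two extents; the dominant extent is certain
(`W′ = 1`) while the dominated one keeps the intersection height 0.4286, so
the normalized weights are (0.70, 0.30) — fuzzy overlap preserves weight
that a crisp judgment would drive to zero.

The `examples/` directory holds one short script per capability: the
linguistic scale and TFN arithmetic, single-matrix extent analysis, the
published priority tables re-ranked and composed into global weights, a
full simulated 22-expert panel run, and a Monte-Carlo rank-recovery
experiment. The command line mirrors the same pipeline for file-based use:

```sh
fuzzyahp simulate --items 8 --experts 22 --noise 0.2 --seed 7 --out run/
fuzzyahp weights  --panel run/panel.tsv --out run/
fuzzyahp rank     --weights run/ --out run/
fuzzyahp recover  --items 8 --replicates 200 --seed 7 --out run/
```

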