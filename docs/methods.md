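# Methods

`fuzzyahp` implements the extent-analysis variant of the fuzzy analytic
hierarchy process (fuzzy AHP) for prioritizing the criteria of a two-level
decision hierarchy — the setting in which it was applied to rank the factors
and subfactors driving the development of military hospital beds — together
with a synthetic expert-panel generator that makes the whole pipeline
testable against known ground truth.

## Model and procedure

**Judgments.** An expert compares items pairwise on a nine-rung linguistic
ladder ("equally important" … "extremely more important"). Each rung maps to
a triangular fuzzy number (TFN) `(l, m, u)` with `0 < l ≤ m ≤ u`; the mirror
cell holds the fuzzy reciprocal `(1/u, 1/m, 1/l)`. A judgment matrix is
valid when its diagonal is `(1, 1, 1)` and every `(j, i)` entry is the fuzzy
reciprocal of `(i, j)` within 0.01 per component — the tolerance that lets
matrices keyed in from 2-decimal printed reciprocals validate. TFN
arithmetic is the standard componentwise triangular approximation
(`+`, `×` componentwise; inversion swaps and reciprocates the bounds);
internal arithmetic is never rounded, and half-up rounding to 2 decimals is
applied only when comparing against printed values.

The stored reciprocal of the extreme rung `(7, 9, 9)` is the conventional
printed triple `(0.11, 0.11, 0.13)`, although `1/7` rounds to `0.14`. The
package always computes reciprocals analytically and records this single
printed anomaly as data (`PRINTED_RECIPROCAL_ANOMALIES`) rather than
propagating it into arithmetic.

**Group aggregation.** A panel's matrices for a node are pooled cell-by-cell
with the componentwise geometric mean — the only standard pooling rule that
preserves fuzzy reciprocity exactly, which downstream validation requires.
A componentwise arithmetic mean is available behind a flag for sensitivity
analysis; because it does not preserve reciprocity, its output's lower
triangle is recomputed from the upper. Aggregation acts on judgments, before
extent analysis, so the pooled matrix feeds the same single-matrix procedure
as an individual expert's would. How the original 22-expert study combined
its questionnaires is not recorded; the geometric mean is this package's
documented convention, not a claim about that study.

**Extent analysis.** For an `n × n` matrix `M`:

1. synthetic extents `S_k = (Σ_j M_kj) ⊗ (Σ_i Σ_j M_ij)^(-1)`; the modal
   components of the `S_k` sum to exactly 1 (algebraic identity, used as an
   internal sanity invariant);
2. possibility degrees `V(S_i ≥ S_k)`: 1 when `m_i ≥ m_k`, 0 when the
   supports are disjoint or merely touch (`u_i ≤ l_k`), otherwise the
   intersection height `(u_i − l_k) / ((u_i − l_k) + (m_k − m_i))`, which
   lies strictly in (0, 1);
3. non-normal weights `W′_i = min_{k≠i} V(S_i ≥ S_k)`, normalized by their
   sum to give `W`.

Sum-normalization of `W′` is a package convention consistent with published
block scores summing to ≈1. An all-zero `W′` would make normalization
impossible and raises `DegenerateWeightsError`; for a valid matrix this is
actually unreachable (the extent with the largest mode always has `W′ = 1`),
so the error is purely defensive. What *is* reachable — and deliberately
surfaced rather than masked — is the zero-weight pathology: a strongly
dominated item whose extent's support lies entirely below a rival's receives
weight exactly 0. Crisp judgments (degenerate TFNs `l = m = u`) make this
extreme: one crisp `(5, 5, 5)` judgment drives the dominated item to 0.

**Ranking.** Scores are ranked with the dense descending convention: the
highest score takes priority 1, tied scores (exact equality on the stored
values) share a priority, and the next distinct score continues at the next
integer. This is the only convention that reproduces the published
subfactor table, whose demographic block ranks 5, 5, 6 where competition
ranking would print 5, 5, 7. Ties are reported as shared ranks, never
broken arbitrarily. Global leaf weights are the product of local weights
down the branch; the published F7 block's printed scores sum to 0.959
(every other block sums to 0.999–1.001), so sibling-sum checks on printed
data use a 0.05 tolerance while computed weights are held to 1e-6.

## Synthetic panels

The generator works backwards from a known truth so recovery can be
measured:

- **Truth sampler** — symmetric Dirichlet. `concentration` (default **3.0**)
  is the single spread knob: at 8 items the median best-to-worst weight
  ratio is ≈5.6 with IQR ≈4–8, matching the spread the published factor
  table exhibits (0.249/0.040 ≈ 6.2) while keeping most ideal judgments on
  the ladder rather than clipped at rung 9.
- **Encoding** — the true ratio `w_i/w_j` is rounded half-up to the nearest
  integer rung, clipped to [1, 9]; ratios below 1 encode as the reciprocal
  orientation of the inverse intensity. Even rungs are the four
  "intermediate" verbal grades, odd rungs the five pure ones, so all nine
  rows of the scale are exercised.
- **Noise** — ordinal, on the ladder: each of `max_steps` (default 1) trials
  moves the judgment one rung up or down with probability
  `step_probability`. The ladder is signed (stepping below "equally
  important" crosses into reciprocal territory) and clipped at ±rung 9, so
  every perturbed judgment is a legal scale entry and every generated matrix
  is valid by construction. Reciprocal cells are filled analytically, never
  perturbed independently.
- **Panel size** — default 22 experts, the size of the expert panel in the
  study this package emulates.

What the generator does **not** model: correlated experts (all perturbations
are independent), systematic bias, partially completed questionnaires, and
intransitive judgment patterns beyond what single-rung noise induces. A
passing recovery suite therefore shows the pipeline is correct and robust to
independent ordinal noise — not that real expert panels behave this way.

### Information limits of the nine-rung ladder

Encoding continuous weights on nine rungs is lossy in two distinct ways,
and both show up as *ties, never inversions* in recovered rankings:

1. **Quantization.** Any weight ratio below 1.5 rounds to "equally
   important", so items that close in truth produce identical judgment rows
   and tie on recovery. For Dirichlet truths at n = 8 this happens in most
   draws; exact dense-rank recovery of a continuous truth is therefore not
   achievable in general, even at zero noise (measured exact-match rates:
   ≈40% at n = 4, ≈16% at n = 8).
2. **Zero-weight collapse.** Extent analysis assigns weight exactly 0 to
   every strongly dominated item, merging the tail of a skewed truth.

Across 100 zero-noise runs (50 seeds × n ∈ {4, 8}) the recovered order
never strictly inverted a true pairwise order, and truths whose ratios
occupy distinct rungs without extreme dominance are recovered exactly. The
stochastic validation bar for noisy panels — 8 items, 22 experts, one
±1-rung step with probability 0.2, 200 replicates — is a median Spearman
correlation of at least 0.9 between true and recovered weights; the
pipeline measures ≈0.98.

## Numerical choices

- Possibility degrees with `u_1 = l_2` exactly (touching supports, `m_1 <
  m_2`) return 0: the intersection height is zero and this avoids 0/0.
- Half-up decimal rounding (not banker's) wherever values are compared with
  printed tables.
- Reciprocity tolerance 0.01 per component on input matrices; geometric-mean
  aggregation preserves reciprocity to ≈1e-15 and is validated at 1e-12 in
  tests.
- Tie detection in ranking uses exact float equality; fixture scores are
  stored at the 3 printed decimals, so printed ties are exact ties.
- Randomness flows through `numpy.random.Generator`; replicate streams are
  spawned from a `SeedSequence` so experiments are reproducible and
  per-replicate independent.

## Problem sizes

Test-suite defaults: the possibility-degree oracle cross-check uses 1,000
random TFN pairs against a two-stage 60,000-point grid search (agreement
within 1e-4); the extent identity runs over 500 random matrices at
n = 2…9; recovery suites use 4–8 items, up to 22 experts, and 100–200
Monte-Carlo replicates. All are desk-scale: the full suite runs in well
under a minute.

## Known limitations

- Extent analysis itself is contested in the decision-analysis literature
  precisely because of the zero-weight pathology; this package implements
  it faithfully and surfaces the pathology instead of patching it.
  Eigenvector, fuzzy-preference-programming, and logarithmic least-squares
  prioritization are out of scope.
- Hierarchies deeper than goal → factor → subfactor and an alternatives
  layer are not supported; the method here ranks criteria only.
- Consistency-ratio machinery for judgment matrices is not implemented.
- The long-format panel file stores only ladder-valued judgments; pooled
  (geometric-mean) matrices are written as full long-format or JSON grids
  instead.
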