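"""Monte-Carlo rank recovery under increasing questionnaire noise.

For each noise level, 100 replicates draw a fresh 8-item truth, simulate a
22-expert panel, and measure the Spearman correlation between the true and
recovered weight vectors.  Noise is the probability that a judgment moves
one rung on the linguistic ladder; even heavy noise is damped by pooling
22 experts.
"""

from fuzzyahp import NoiseModel, recovery_experiment, summarize_recovery

print("noise  median_rho  mean_rho  exact_rank_match")
for p in (0.0, 0.2, 0.5, 1.0):
    res = recovery_experiment(
        n_items=8,
        n_experts=22,
        noise=NoiseModel(step_probability=p, max_steps=1),
        replicates=100,
        seed=42,
    )
    s = summarize_recovery(res)
    print(f"{p:5.1f}  {s['median_spearman']:10.3f}  {s['mean_spearman']:8.3f}  "
          f"{s['exact_match_rate']:16.2f}")
print("\nMedian correlations stay high because the geometric-mean pool of 22")
print("experts averages out single-rung errors; exact dense-rank matches are")
print("rarer since near-equal weights are indistinguishable on a 9-rung scale.")
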