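"""Dense priority ranking and hierarchical weight composition.

Loads the published factor/subfactor tables for military hospital-bed
development, re-derives every priority column with the dense descending
ranking rule (ties share a rank; the next distinct score continues at the
next integer), and composes local weights into global leaf weights.
"""

from fuzzyahp import default_hierarchy, fixtures, global_weights, rank_dense

tabs = fixtures()

factors = tabs.table2
recomputed = rank_dense(factors["score"], items=factors["code"])
print("factor                                      score  printed  recomputed")
for (_, row), prio in zip(factors.iterrows(), recomputed.priorities):
    print(f"{row['label']:<42} {row['score']:.3f}  {row['priority']:>7}  {prio:>10}")

f2 = tabs.table3["F2"]
ranks = [int(r) for r in rank_dense(f2["score"], items=f2["code"]).priorities]
print(f"\ndemographic block ties: scores {list(f2['score'])}")
print(f"dense priorities:              {ranks} (5, 5 share; next is 6)")

root = default_hierarchy()
root.set_local_weights({c: s for c, _l, s, _p in tabs.factors})
for fcode, block in tabs.subfactors.items():
    root.child(fcode).set_local_weights({c: s for c, _l, s, _p in block})
gw = global_weights(root, tol=0.05).nlargest(5, "global_weight")
print("\ntop-5 subfactors by global weight (factor weight x local weight):")
print(gw.round(4).to_string(index=False))
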