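"""Fuzzy judgment scale and triangular arithmetic.

Builds the nine-level linguistic ladder, shows the componentwise TFN
operations, and recomputes each rung's reciprocal analytically.  The
printed table shows that 2-decimal rounding of (1/u, 1/m, 1/l) reproduces
the conventional reciprocal triples (one upper component of the extreme
rung is customarily printed as 0.13 although 1/7 rounds to 0.14).
"""

from fuzzyahp import SCALE, TriangularFuzzyNumber as TFN, tfn_inv

a, b = TFN(1, 2, 3), TFN(1, 3, 5)
print(f"{a.astuple()} + {b.astuple()} = {(a + b).astuple()}")
print(f"{a.astuple()} * {b.astuple()} = {(a * b).astuple()}")
print(f"inverse of {b.astuple()} = {tfn_inv(b).rounded(2).astuple()}")
print()
print(f"{'definition':<52} {'forward':<12} reciprocal (computed)")
for entry in SCALE:
    rec = tfn_inv(entry.forward).rounded(2)
    print(f"{entry.label:<52} {str(entry.forward.astuple()):<12} {rec.astuple()}")
print()
print("Each reciprocal above is (1/u, 1/m, 1/l) of the forward triple,")
print("rounded half-up to the 2 decimals used on questionnaire forms.")
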