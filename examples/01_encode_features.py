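"""Encode a tiny hand-checkable sequence as PseKGCC features.

The sequence GGGCCCAAATTT splits (epsilon=0.25, delta=0.75) into GGG /
CCCAAA / TTT, which reduce to GGG / CCC*** / ***. With k=2, lambda=1 and
w=0.5 the front window is pure GG with maximal positive skew, the middle is
C-rich with negative skew, and the rear is all-wildcard and skew-neutral.
"""

from psekgcc import DnaRecord, PsekgccParams, encode_psekgcc, feature_names

record = DnaRecord(id="demo", sequence="GGGCCCAAATTT")
params = PsekgccParams(epsilon=0.25, delta=0.75, k=2, lam=1, w=0.5)

vector = encode_psekgcc(record, params)
print(f"feature dimension: {vector.dimension}  (= 3 * (3^{params.k} + {params.lam}))")
print("nonzero components:")
for name, value in zip(feature_names(params), vector.phi):
    if abs(value) > 1e-15:
        print(f"  {name:>15s} = {value:+.4f}")
print(
    "\nEach window block sums to 1; theta components carry the window's GC\n"
    "skew (positive = G-rich, negative = C-rich), weighted by w."
)
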