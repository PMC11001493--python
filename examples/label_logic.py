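"""Left-hand/right-hand labels and clash detection from per-threshold calls.

Each per-threshold classifier answers "stable at >= T degrees C?" on its
own, so the ordered call vector need not be internally consistent.  The
left-hand label follows the leading run of positive calls; the right-hand
label follows the highest positive call anywhere.  They agree exactly when
the vector is monotone non-increasing — then both name the highest
temperature range the protein is predicted to withstand.
"""

from itertools import product

from thermoclass import DEFAULT_THRESHOLDS, enumerate_consistency, left_right_labels

EXAMPLES = [
    [0, 0, 0, 0, 0, 0],  # nothing called stable
    [1, 1, 1, 0, 0, 0],  # consistent: stable up to the 50-55 C range
    [1, 1, 1, 1, 1, 1],  # consistent: stable at 65 C and beyond
    [0, 0, 1, 0, 0, 0],  # inconsistent: only the 50 C classifier fired
    [1, 0, 1, 1, 0, 0],  # inconsistent: hole in the leading run
]

print(f"thresholds: {[f'{t:g}C' for t in DEFAULT_THRESHOLDS]}\n")
for calls in EXAMPLES:
    left, right, clash = left_right_labels(calls, DEFAULT_THRESHOLDS)
    flag = "CLASH" if clash else "ok"
    print(f"calls {calls} -> left {left.name:>8}  right {right.name:>8}  {flag}")

n = len(DEFAULT_THRESHOLDS)
consistent = enumerate_consistency(n)
print(
    f"\n{consistent} of the {2**n} possible call vectors are clash-free "
    f"(exactly the monotone ones: one per temperature range)."
)

# cross-check by brute force over every vector
monotone = sum(
    all(a >= b for a, b in zip(v, v[1:])) for v in product((0, 1), repeat=n)
)
print(f"brute-force count of monotone vectors: {monotone}")
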