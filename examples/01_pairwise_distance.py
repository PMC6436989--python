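"""Estimate the evolutionary distance between two simulated proteomes.

Simulates an aligned, indel-free protein pair at a known distance, then
runs the full alignment-free estimator on the two sequences as if they were
unrelated proteome files, and compares the estimate with the Kimura
distance computed from the true alignment.
"""

from spacedist import (
    alignment_kimura_oracle,
    blosum62,
    compare_proteomes,
    estimate_pair_distance,
    generate_pattern_set,
    simulate_pair,
)
from spacedist.simulate import pair_to_proteomes

D_TRUE = 0.5  # substitutions per site used by the generator

s1, s2 = simulate_pair(length=20000, d=D_TRUE, model="jtt", seed=42)
prot1, prot2 = pair_to_proteomes(s1, s2)

# default parameters: 5 patterns, weight 6, 40 don't-care columns, T = 0
patterns = generate_pattern_set(m=5, w=6, ell=46, seed=42)
matches, spamogram = compare_proteomes(prot1, prot2, patterns, blosum62(), threshold=0)
result = estimate_pair_distance(matches)

print(f"generator distance          : {D_TRUE}")
print(f"selected spaced-word matches: {result.n_matches}")
print(f"mismatch fraction p         : {result.p:.4f}")
print(f"estimated distance d        : {result.d:.4f}")
print(f"alignment-based oracle      : {alignment_kimura_oracle(s1, s2):.4f}")
print()
print("The estimate is derived only from the don't-care columns of filtered")
print("spaced-word matches, yet it reproduces the distance an alignment of")
print("the same pair would give.")
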