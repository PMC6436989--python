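# Methods

## Distance model

`spacedist` estimates the evolutionary distance between two proteomes as
substitutions per site, without aligning them. The estimator assumes that
two related proteomes share many homologous segments long enough (ℓ = 46 by
default) to contain spaced-word matches, that substitutions at the
don't-care columns of such matches are representative of the genome-wide
substitution process, and that indels and rearrangements only reduce the
number of usable windows rather than bias the surviving columns. Under
those assumptions the mismatch fraction p observed at pooled don't-care
columns estimates the per-site mismatch probability of an alignment of the
homologous regions, and Kimura's closed form

    d = −ln(1 − p − 0.2 p²)

converts it to an approximate PAM distance. The formula is monotone on
[0, p_max) with p_max = (√1.8 − 1)/0.4 ≈ 0.8536, the positive root of
1 − p − 0.2p²; pairs at or beyond p_max are reported as `saturated` rather
than given a finite value.

Candidate matches are filtered before anything else: a candidate whose
don't-care BLOSUM62 score is below T is treated as a background key
collision. Filtering happens *before* the greedy one-to-one selection so a
background candidate can never block a homologous one sharing an endpoint.
The greedy step then walks the remaining candidates of each spaced word in
descending score order (ties broken by occurrence coordinates, fully
deterministic) and accepts a candidate only if neither of its two window
occurrences is already used. This yields a matching — each occurrence in at
most one selected match — which prevents repeat families from dominating
the mismatch pool.

Mismatches and columns are pooled across all selected matches of **all** m
patterns into a single p per proteome pair, rather than averaging
per-pattern distances; pooling maximizes the effective column count behind
one estimate and weights every column equally.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| w (weight) | 6 | match positions per pattern; 20⁶ ≈ 6.4·10⁷ distinct keys keeps random collisions rare while leaving enough matches |
| ℓ − w | 40 | don't-care columns per match; enough columns for a stable per-match score and mismatch count |
| m | 5 | patterns per set; more patterns yield more matches and statistically more stable estimates |
| T | 0 | score threshold; sits in the valley between the background and homologous peaks of the spamogram |
| seed | 42 | pattern-set generation is probabilistic; a fixed default makes runs reproducible, `--random-seed` opts out |
| distance ceiling | 10.0 | value assigned (with a status flag and warning) to pairs with no matches or saturated p, so heterogeneous datasets still produce a full matrix and tree |

All defaults are overridable by one CLI flag each.

## Pattern-set optimization

Patterns are canonical: the first position is always a match position
(spaced words are shift-invariant, so a leading don't-care column only
duplicates a shifted pattern), while trailing don't-care positions are kept
because don't-care columns carry scoring information. Sets are optimized by
hill climbing on the overlap complexity Σ 2^σ(s) over all relative shifts s
of all pattern pairs, where σ(s) counts coinciding match positions; for a
pattern against itself the zero shift is excluded as a constant. One move
swaps a random match position (never the leading one) with a random
don't-care position in one pattern and is accepted iff the objective
strictly decreases and all patterns stay distinct; the default budget is
5,000 proposals. The neighborhood, acceptance rule and budget are this
package's choices — the optimization literature offers several variants —
and are fixed for determinism; the objective value is monotonically
non-increasing by construction.

## Matching pipeline

Sequences are encoded to integer codes 0–19; every non-canonical character
(B, J, O, U, X, Z, stop, gap, …) is kept in place but flagged ambiguous so
coordinates are stable, and any window containing an ambiguous residue at
*any* position is excluded from extraction — partial scoring of ambiguous
columns would require an arbitrary substitution-score convention. Each
proteome is concatenated with ℓ ambiguous sentinels between sequences, so
windows can never span a sequence boundary. Spaced words are packed base-20
into 64-bit integer keys (w ≤ 13), occurrence lists are sorted by key, and
buckets are joined by sorted-key intersection. Buckets where the key occurs
once on both sides bypass the greedy step entirely; general buckets run the
per-bucket greedy. Each unordered taxon pair is always compared with the
lexicographically smaller taxon name as side 1, making results independent
of argument order; taxon pairs are independent work units and output is
bit-identical regardless of the `--threads` value (the current
implementation processes pairs sequentially — at the problem sizes this
package targets, the vectorized matcher is not wall-clock-bound by pair
parallelism).

The spamogram records the scores of one-to-one-selected matches *before*
threshold filtering, so both the background and the homologous peak remain
visible; the returned match list applies the threshold.

A brute-force O(n·n′·ℓ) enumerator (`enumerate_candidates_bruteforce`)
re-derives all candidates by direct window comparison and is used in the
tests to verify the indexed pipeline exactly on small inputs.

## Tree building and comparison

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q-criterion;
ties in Q are broken by the lexicographically smallest joined pair, keyed by
the smallest leaf label in each cluster, so the output is deterministic and
insensitive to input order. Branch lengths use the standard limb-length
formulas; negative lengths (possible on non-additive input) are kept as
computed, with an optional `--clamp-negative`. On an additive matrix the
algorithm provably recovers the generating tree, topology and branch
lengths; the tests exercise this on 100 random trees and cross-check the
topology against dendropy's independent NJ implementation.

Robinson–Foulds distances count the symmetric difference of non-trivial
bipartitions (dendropy's bipartition encoding); polytomies are compared
as-is. The relative RF divides by the maximum 2n − 6 for n taxa and is
rendered half-up at two decimals where tables require rounding.

## Simulator

The evaluation generator produces indel-free aligned pairs under a
reversible 20-state continuous-time Markov model scaled to one expected
substitution per site per unit time. The first sequence is drawn site-wise
from the stationary frequencies and the second evolves from it for time d
via exp(Qd), computed once per d by eigendecomposition of the
√π-symmetrized generator — by reversibility this equals evolving both
sequences d/2 from a common ancestor. Two models are built in: `jtt`
(embedded published exchangeability counts and frequencies of the
Jones–Taylor–Thornton model; the realistic default) and `poisson` (uniform
rates/frequencies), which exists because its mismatch curve
E[p] = (19/20)(1 − e^(−20d/19)) is available in closed form and anchors the
generator tests analytically.

The alignment-based oracle applies the same Kimura correction to the
site-wise mismatch fraction of the known alignment — the "true" distance an
alignment-based tool would report for the same pair. Accuracy sweeps run the
*full* estimator (fresh optimized pattern set per replicate, mirroring
independent program runs) against this oracle. The default sweep uses pairs
of length 20,000 with 20 replicates per grid point over d ∈ [0.1, 1.0];
these sizes give standard errors comfortably below the comparison
tolerances while keeping a sweep in the low minutes on one CPU.

### What the generator does and does not emulate

It emulates site-independent substitution at a homogeneous rate on
single-sequence "proteomes". It does **not** produce indels,
across-site rate variation, domain shuffling, gene families/repeats, low
complexity regions, ambiguity characters, or incomplete proteomes — so
passing sweeps demonstrate the estimator's statistical correctness under
its own model assumptions, not robustness to those real-data features.
(Repeat handling and ambiguity handling are instead exercised directly by
the matching unit tests.)

## Numerical and degenerate-input choices

- Distances are stored at full precision; PHYLIP files render 6 decimals
  (relaxed names by default, strict 10-character mode with collision
  detection on request).
- `p = 0` maps to exactly `d = 0`; `p ≥ p_max` and zero-match pairs map to
  the ceiling with status `saturated` / `no_matches` plus a warning.
- Rounding for reported relative RF uses half-up (ties away from zero), the
  usual table convention, rather than banker's rounding.
- NJ on fewer than 3 taxa, duplicate taxon names, empty FASTA records and
  leaf-set mismatches in tree comparison raise errors rather than guess.

## Known limitations

- Distances beyond ≈ 1.6 substitutions per site approach spamogram overlap
  and saturation; estimates there are increasingly noisy and eventually
  flagged.
- The greedy per-bucket matching is maximal, not maximum-weight; this is
  deliberate (deterministic, linear after sorting) and matches the method's
  definition, but specific tie configurations could select marginally
  different column pools than another implementation would.
- BLOSUM62 is fixed as the scoring matrix (the threshold separates peaks so
  cleanly that the choice matters little); no alternative corrections
  (Poisson, Grishin) are provided.
- DNA input and six-frame translation are out of scope.
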