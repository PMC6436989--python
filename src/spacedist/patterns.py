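"""Binary spaced-seed patterns and overlap-complexity optimization.

A pattern is a 0/1 string of length ``ell``: ``1`` marks a *match* position
(the residue there must be identical in both sequences for a spaced-word
match) and ``0`` a *don't-care* position (the aligned residues there are
scored, not required to match).  The number of match positions is the
pattern's *weight* ``w``.

Pattern sets are optimized by hill climbing on the overlap complexity
objective: sets whose patterns share many match positions under relative
shifts produce strongly correlated spaced-word matches, so lower overlap
complexity means more nearly independent match information.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Pattern",
    "PatternSet",
    "overlap_complexity_pair",
    "set_overlap_complexity",
    "generate_pattern_set",
    "read_pattern_file",
    "write_pattern_file",
]


@dataclass(frozen=True)
class Pattern:
    """An immutable binary match/don't-care pattern.

    Canonical form requires the first position to be a match position;
    trailing don't-care positions are allowed because don't-care columns
    carry scoring information.
    """

    bits: str

    def __post_init__(self) -> None:
        if not self.bits or set(self.bits) - {"0", "1"}:
            raise ValueError(f"pattern must be a nonempty 0/1 string, got {self.bits!r}")
        if self.bits[0] != "1":
            raise ValueError("pattern must start with a match position")

    @property
    def length(self) -> int:
        return len(self.bits)

    @property
    def weight(self) -> int:
        return self.bits.count("1")

    @property
    def match_positions(self) -> np.ndarray:
        """0-based indices of match positions."""
        return np.flatnonzero(np.frombuffer(self.bits.encode(), dtype=np.uint8) == ord("1"))

    @property
    def dontcare_positions(self) -> np.ndarray:
        """0-based indices of don't-care positions."""
        return np.flatnonzero(np.frombuffer(self.bits.encode(), dtype=np.uint8) == ord("0"))

    def as_array(self) -> np.ndarray:
        return (np.frombuffer(self.bits.encode(), dtype=np.uint8) == ord("1")).astype(np.int64)

    def __str__(self) -> str:
        return self.bits

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class PatternSet:
    """A set of distinct patterns sharing one (weight, length) shape."""

    patterns: tuple[Pattern, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("pattern set must contain at least one pattern")
        shapes = {(p.weight, p.length) for p in self.patterns}
        if len(shapes) != 1:
            raise ValueError(f"all patterns must share weight and length, got shapes {shapes}")
        if len({p.bits for p in self.patterns}) != len(self.patterns):
            raise ValueError("patterns must be pairwise distinct")
        object.__setattr__(self, "patterns", tuple(self.patterns))

    @property
    def m(self) -> int:
        return len(self.patterns)

    @property
    def weight(self) -> int:
        return self.patterns[0].weight

    @property
    def length(self) -> int:
        return self.patterns[0].length

    def __iter__(self) -> Iterator[Pattern]:
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)


def _to_bit_array(p: "Pattern | str | np.ndarray") -> np.ndarray:
    if isinstance(p, Pattern):
        return p.as_array()
    if isinstance(p, str):
        return np.frombuffer(p.encode(), dtype=np.uint8).astype(np.int64) - ord("0")
    return np.asarray(p, dtype=np.int64)


def overlap_complexity_pair(p: "Pattern | str", q: "Pattern | str", *, self_pair: bool = False) -> int:
    """Overlap complexity of an unordered pattern pair (symmetric).

    Sums ``2**sigma(s)`` over all relative shifts ``s``, where ``sigma(s)``
    counts positions where a match position of ``p`` coincides with a match
    position of ``q`` shifted by ``s``.  With ``self_pair=True`` the zero
    shift is excluded: for a pattern against itself that term is the
    constant ``2**w`` and carries no optimization signal.

    Accepts :class:`Pattern` objects or raw 0/1 strings (the raw form also
    admits non-canonical layouts, useful for analysis).
    """
    return _oc_pair_raw(_to_bit_array(p), _to_bit_array(q), self_pair=self_pair)


def _oc_pair_raw(a: np.ndarray, b: np.ndarray, self_pair: bool) -> int:
    # np.correlate(a, b, "full")[k] is sigma at shift s = k - (len(b) - 1)
    sigma = np.correlate(a, b, mode="full")
    if self_pair:
        sigma = np.delete(sigma, len(b) - 1)
    return int(np.exp2(sigma).astype(np.int64).sum())


def set_overlap_complexity(ps: PatternSet) -> int:
    """Total overlap complexity: sum over unordered pairs including self-pairs."""
    arrays = [p.as_array() for p in ps]
    total = 0
    for i in range(len(arrays)):
        for j in range(i, len(arrays)):
            total += _oc_pair_raw(arrays[i], arrays[j], self_pair=(i == j))
    return total


def _n_canonical_patterns(w: int, ell: int) -> int:
    """Number of distinct patterns with a leading match position."""
    from math import comb

    return comb(ell - 1, w - 1)


def _random_pattern(rng: np.random.Generator, w: int, ell: int) -> np.ndarray:
    bits = np.zeros(ell, dtype=np.int64)
    bits[0] = 1
    if w > 1:
        bits[1 + rng.choice(ell - 1, size=w - 1, replace=False)] = 1
    return bits


def _bits_to_pattern(bits: np.ndarray) -> Pattern:
    return Pattern("".join("1" if b else "0" for b in bits))


def generate_pattern_set(
    m: int,
    w: int,
    ell: int,
    seed: int = 42,
    iterations: int = 5000,
) -> PatternSet:
    """Generate ``m`` distinct patterns of weight ``w`` and length ``ell``
    by hill climbing on the set overlap complexity.

    The neighborhood move swaps one randomly chosen match position (never
    the leading one) with one randomly chosen don't-care position in one
    randomly chosen pattern; a move is accepted iff it keeps all patterns
    distinct and strictly decreases the objective.  Deterministic for fixed
    arguments.
    """
    if not (1 <= w <= ell):
        raise ValueError(f"need 1 <= w <= ell, got w={w}, ell={ell}")
    if m < 1:
        raise ValueError("m must be >= 1")
    if _n_canonical_patterns(w, ell) < m:
        raise ValueError(
            f"only {_n_canonical_patterns(w, ell)} distinct patterns of weight {w}, "
            f"length {ell} exist; cannot draw {m}"
        )

    rng = np.random.default_rng(seed)

    # distinct random initial set
    chosen: list[np.ndarray] = []
    keys: set[bytes] = set()
    while len(chosen) < m:
        bits = _random_pattern(rng, w, ell)
        key = bits.tobytes()
        if key not in keys:
            keys.add(key)
            chosen.append(bits)

    if w == ell or w == 1 or iterations <= 0 or _n_canonical_patterns(w, ell) == m:
        return PatternSet(tuple(_bits_to_pattern(b) for b in chosen), seed=seed)

    # cache pairwise OC terms; term[i][j] for i <= j
    def pair_term(i: int, j: int) -> int:
        return _oc_pair_raw(chosen[min(i, j)], chosen[max(i, j)], self_pair=(i == j))

    terms = {(i, j): pair_term(i, j) for i in range(m) for j in range(i, m)}

    for _ in range(iterations):
        k = int(rng.integers(m))
        bits = chosen[k]
        match_idx = np.flatnonzero(bits[1:] == 1) + 1
        dc_idx = np.flatnonzero(bits == 0)
        if match_idx.size == 0 or dc_idx.size == 0:
            continue
        i_on = int(match_idx[rng.integers(match_idx.size)])
        i_off = int(dc_idx[rng.integers(dc_idx.size)])
        cand = bits.copy()
        cand[i_on], cand[i_off] = 0, 1
        key = cand.tobytes()
        if key in keys:
            continue
        old = sum(terms[(min(k, j), max(k, j))] for j in range(m))
        new_terms = {
            (min(k, j), max(k, j)): _oc_pair_raw(cand, cand, self_pair=True)
            if j == k
            else _oc_pair_raw(cand, chosen[j], self_pair=False)
            for j in range(m)
        }
        if sum(new_terms.values()) < old:
            keys.discard(bits.tobytes())
            keys.add(key)
            chosen[k] = cand
            terms.update(new_terms)

    return PatternSet(tuple(_bits_to_pattern(b) for b in chosen), seed=seed)


def read_pattern_file(path: str | Path) -> PatternSet:
    """Read a pattern set from a text file, one 0/1 string per line.

    Blank lines and lines starting with ``#`` are ignored.
    """
    pats = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pats.append(Pattern(line))
    if not pats:
        raise ValueError(f"no patterns found in {path}")
    return PatternSet(tuple(pats))


def write_pattern_file(ps: PatternSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{p.bits}\n" for p in ps))
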