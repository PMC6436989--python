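"""Spaced-word extraction, match scoring, filtering and one-to-one selection.

Given a binary pattern, a *spaced word* occurs at a window of a protein
sequence by reading the residues at the pattern's match positions.  Two
windows in two proteomes with the same spaced word form a candidate
*spaced-word match*: a gap-free micro-alignment of the two windows.  Its
score is the sum of BLOSUM62 substitution scores of the residue pairs
aligned at the don't-care positions; homologous matches score high,
background matches cluster around the random expectation.  Candidates
scoring below a threshold ``T`` are discarded, and the survivors are thinned
to a one-to-one matching (greedy, by descending score) so repeated regions
are not over-counted.  The score histogram of the selected matches — the
*spamogram* — is typically bimodal, which is what makes the threshold
filter work.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .patterns import Pattern, PatternSet
from .proteome import AMBIGUOUS_CODE, AMINO_ACIDS, Proteome, encode_sequence

__all__ = [
    "ScoringMatrix",
    "blosum62",
    "SpacedWordOccurrence",
    "SpacedWordMatch",
    "Spamogram",
    "MatchCollection",
    "extract_spaced_words",
    "score_match",
    "select_one_to_one",
    "compare_proteomes",
    "enumerate_candidates",
    "enumerate_candidates_bruteforce",
]

DEFAULT_THRESHOLD = 0


@dataclass(frozen=True)
class ScoringMatrix:
    """A 20x20 integer substitution matrix indexed by amino-acid code."""

    name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.shape != (20, 20):
            raise ValueError("scoring matrix must be 20x20")
        if not np.array_equal(s, s.T):
            raise ValueError("scoring matrix must be symmetric")
        # each residue must score best against itself within its row —
        # required for the self-match/maximal-score invariants downstream
        if not np.all(np.diag(s) >= s.max(axis=1)):
            raise ValueError("diagonal must dominate each row")
        object.__setattr__(self, "scores", s.astype(np.int64))

    def score(self, a: str, b: str) -> int:
        ia, ib = AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)
        return int(self.scores[ia, ib])


_BLOSUM62: ScoringMatrix | None = None


def blosum62() -> ScoringMatrix:
    """The NCBI BLOSUM62 matrix restricted to the 20 canonical residues."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        raw = substitution_matrices.load("BLOSUM62")
        s = np.zeros((20, 20), dtype=np.int64)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                s[i, j] = int(raw[a, b])
        _BLOSUM62 = ScoringMatrix("BLOSUM62", s)
    return _BLOSUM62


class SpacedWordOccurrence(NamedTuple):
    """One length-``ell`` window of a proteome, read under a pattern.

    ``key`` is the spaced word itself: the residues at the pattern's match
    positions.  ``window`` is the full window so that matches can be scored
    from the occurrence alone.  Offsets are 0-based.
    """

    seq_index: int
    offset: int
    key: str
    window: str


class SpacedWordMatch(NamedTuple):
    """A scored gap-free micro-alignment between two occurrences."""

    pattern_index: int
    occ1: SpacedWordOccurrence
    occ2: SpacedWordOccurrence
    score: int
    dontcare_mismatches: int
    dontcare_columns: int


class Spamogram(dict):
    """Histogram mapping match score -> count of one-to-one selected matches
    (before threshold filtering), pooled over all patterns of one pair."""

    def add_scores(self, scores: np.ndarray) -> None:
        vals, counts = np.unique(scores, return_counts=True)
        for v, c in zip(vals.tolist(), counts.tolist()):
            self[int(v)] = self.get(int(v), 0) + int(c)

    @property
    def total(self) -> int:
        return sum(self.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("score\tcount\n")
            for s in sorted(self):
                fh.write(f"{s}\t{self[s]}\n")


# ---------------------------------------------------------------------------
# vectorized internals
# ---------------------------------------------------------------------------


class _EncodedProteome:
    """Concatenated int8 codes of one proteome with sentinel spacers.

    Sequences are separated by ``ell`` ambiguous sentinels so windows can
    never span a sequence boundary: any window crossing a boundary contains
    a sentinel and is dropped by the ambiguity filter.
    """

    def __init__(self, prot: Proteome, ell: int) -> None:
        self.ell = ell
        parts: list[np.ndarray] = []
        starts: list[int] = []
        spacer = np.full(ell, AMBIGUOUS_CODE, dtype=np.int8)
        pos = 0
        for seq in prot.sequences:
            starts.append(pos)
            codes = encode_sequence(seq)
            parts.append(codes)
            parts.append(spacer)
            pos += len(codes) + ell
        self.codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)
        self.seq_starts = np.asarray(starts, dtype=np.int64)
        self.seq_lengths = np.asarray([len(s) for s in prot.sequences], dtype=np.int64)
        bad = (self.codes == AMBIGUOUS_CODE).astype(np.int64)
        self._bad_cumsum = np.concatenate([[0], np.cumsum(bad)])

    def valid_offsets(self) -> np.ndarray:
        """Concatenated offsets of all ambiguity-free windows of length ell."""
        n = len(self.codes)
        if n < self.ell:
            return np.empty(0, dtype=np.int64)
        window_bad = self._bad_cumsum[self.ell :] - self._bad_cumsum[: n - self.ell + 1]
        return np.flatnonzero(window_bad == 0).astype(np.int64)

    def to_local(self, offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map concatenated offsets to (seq_index, within-sequence offset)."""
        idx = np.searchsorted(self.seq_starts, offsets, side="right") - 1
        return idx, offsets - self.seq_starts[idx]


def _pack_keys(codes: np.ndarray, offsets: np.ndarray, match_pos: np.ndarray) -> np.ndarray:
    """Pack the residues at match positions into base-20 integer keys."""
    w = len(match_pos)
    if w > 13:
        raise ValueError("pattern weight > 13 does not fit a 64-bit packed key")
    powers = 20 ** np.arange(w - 1, -1, -1, dtype=np.int64)
    window_codes = codes[offsets[:, None] + match_pos].astype(np.int64)
    return window_codes @ powers


def _pattern_occurrences(enc: _EncodedProteome, pattern: Pattern) -> tuple[np.ndarray, np.ndarray]:
    """(offsets, keys) of all valid windows, sorted by (key, offset)."""
    offsets = enc.valid_offsets()
    if offsets.size == 0:
        return offsets, offsets.copy()
    keys = _pack_keys(enc.codes, offsets, pattern.match_positions)
    order = np.argsort(keys, kind="stable")  # offsets already ascending
    return offsets[order], keys[order]


def _score_candidates(
    enc1: _EncodedProteome,
    enc2: _EncodedProteome,
    off1: np.ndarray,
    off2: np.ndarray,
    dc_pos: np.ndarray,
    scores_tab: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized don't-care score and mismatch count for candidate pairs."""
    if off1.size == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy()
    if dc_pos.size == 0:
        z = np.zeros(off1.size, dtype=np.int64)
        return z, z.copy()
    a = enc1.codes[off1[:, None] + dc_pos].astype(np.int64)
    b = enc2.codes[off2[:, None] + dc_pos].astype(np.int64)
    return scores_tab[a, b].sum(axis=1), (a != b).sum(axis=1)


def _greedy_one_to_one(order: np.ndarray, off1: np.ndarray, off2: np.ndarray) -> np.ndarray:
    """Indices of greedily accepted candidates given a precomputed order."""
    used1: set[int] = set()
    used2: set[int] = set()
    accepted = []
    for k in order:
        o1, o2 = int(off1[k]), int(off2[k])
        if o1 in used1 or o2 in used2:
            continue
        used1.add(o1)
        used2.add(o2)
        accepted.append(k)
    return np.asarray(accepted, dtype=np.int64)


def _candidate_order(scores: np.ndarray, off1: np.ndarray, off2: np.ndarray) -> np.ndarray:
    """Deterministic processing order: score descending, then both offsets
    ascending (sequence index then position, which concatenated offsets
    preserve)."""
    return np.lexsort((off2, off1, -scores))


@dataclass
class _PairMatches:
    """Selected matches of one proteome pair under one pattern (array form)."""

    pattern_index: int
    off1: np.ndarray
    off2: np.ndarray
    scores: np.ndarray
    mismatches: np.ndarray


class MatchCollection:
    """All threshold-passing one-to-one selected matches of a proteome pair,
    pooled over the patterns of a pattern set.

    Stored in array form; iterate to obtain :class:`SpacedWordMatch`
    objects (intended for small inputs and reporting).
    """

    def __init__(
        self,
        prot1: Proteome,
        prot2: Proteome,
        pattern_set: PatternSet,
        per_pattern: list[_PairMatches],
        enc1: _EncodedProteome,
        enc2: _EncodedProteome,
    ) -> None:
        self.prot1 = prot1
        self.prot2 = prot2
        self.pattern_set = pattern_set
        self._per_pattern = per_pattern
        self._enc1 = enc1
        self._enc2 = enc2

    def __len__(self) -> int:
        return sum(pm.off1.size for pm in self._per_pattern)

    @property
    def n_matches(self) -> int:
        return len(self)

    @property
    def scores(self) -> np.ndarray:
        return np.concatenate([pm.scores for pm in self._per_pattern]) if self._per_pattern else np.zeros(0, dtype=np.int64)

    @property
    def total_dontcare_columns(self) -> int:
        dc = self.pattern_set.length - self.pattern_set.weight
        return len(self) * dc

    @property
    def total_mismatches(self) -> int:
        return int(sum(pm.mismatches.sum() for pm in self._per_pattern))

    def __iter__(self) -> Iterator[SpacedWordMatch]:
        ell = self.pattern_set.length
        for pm in self._per_pattern:
            pat = self.pattern_set.patterns[pm.pattern_index]
            s1, l1 = self._enc1.to_local(pm.off1)
            s2, l2 = self._enc2.to_local(pm.off2)
            for i in range(pm.off1.size):
                w1 = self.prot1.sequences[int(s1[i])][int(l1[i]) : int(l1[i]) + ell]
                w2 = self.prot2.sequences[int(s2[i])][int(l2[i]) : int(l2[i]) + ell]
                key = "".join(w1[int(j)] for j in pat.match_positions)
                yield SpacedWordMatch(
                    pattern_index=pm.pattern_index,
                    occ1=SpacedWordOccurrence(int(s1[i]), int(l1[i]), key, w1),
                    occ2=SpacedWordOccurrence(int(s2[i]), int(l2[i]), key, w2),
                    score=int(pm.scores[i]),
                    dontcare_mismatches=int(pm.mismatches[i]),
                    dontcare_columns=ell - self.pattern_set.weight,
                )


# ---------------------------------------------------------------------------
# public object-level API
# ---------------------------------------------------------------------------


def extract_spaced_words(prot: Proteome, pattern: Pattern) -> list[SpacedWordOccurrence]:
    """All spaced-word occurrences of one proteome under one pattern.

    A window qualifies if it lies fully inside a single sequence and is free
    of ambiguous residues.  Output is sorted by key (then position), so
    occurrences of the same spaced word are adjacent.
    """
    enc = _EncodedProteome(prot, pattern.length)
    offsets, _ = _pattern_occurrences(enc, pattern)
    seq_idx, local = enc.to_local(offsets)
    out = []
    mp = pattern.match_positions
    for si, lo in zip(seq_idx.tolist(), local.tolist()):
        window = prot.sequences[si][lo : lo + pattern.length]
        key = "".join(window[int(j)] for j in mp)
        out.append(SpacedWordOccurrence(si, lo, key, window))
    return out


def score_match(
    occ1: SpacedWordOccurrence,
    occ2: SpacedWordOccurrence,
    pattern: Pattern,
    matrix: ScoringMatrix | None = None,
) -> tuple[int, int]:
    """Score one spaced-word match: (don't-care score, mismatch count)."""
    if occ1.key != occ2.key:
        raise ValueError("occurrences are not a spaced-word match (keys differ)")
    matrix = matrix or blosum62()
    score = 0
    mismatches = 0
    for j in pattern.dontcare_positions:
        a, b = occ1.window[int(j)], occ2.window[int(j)]
        score += matrix.score(a, b)
        mismatches += a != b
    return score, mismatches


def select_one_to_one(
    candidates: Sequence[SpacedWordMatch],
    threshold: int = DEFAULT_THRESHOLD,
) -> list[SpacedWordMatch]:
    """Greedy one-to-one selection among candidates sharing one spaced word.

    Candidates below the score threshold are discarded *before* selection so
    a background match can never block a homologous one.  The rest are taken
    in descending score order (ties broken by occurrence coordinates), each
    accepted only if neither of its two occurrences is already used.
    """
    kept = [c for c in candidates if c.score >= threshold]
    kept.sort(
        key=lambda c: (
            -c.score,
            c.occ1.seq_index,
            c.occ1.offset,
            c.occ2.seq_index,
            c.occ2.offset,
        )
    )
    used1: set[tuple[int, int]] = set()
    used2: set[tuple[int, int]] = set()
    out = []
    for c in kept:
        k1 = (c.occ1.seq_index, c.occ1.offset)
        k2 = (c.occ2.seq_index, c.occ2.offset)
        if k1 in used1 or k2 in used2:
            continue
        used1.add(k1)
        used2.add(k2)
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# full pairwise comparison
# ---------------------------------------------------------------------------


def compare_proteomes(
    prot1: Proteome,
    prot2: Proteome,
    pattern_set: PatternSet,
    matrix: ScoringMatrix | None = None,
    threshold: int = DEFAULT_THRESHOLD,
) -> tuple[MatchCollection, Spamogram]:
    """Enumerate, score, filter and one-to-one select spaced-word matches
    between two proteomes, pooled over all patterns of the set.

    Returns the selected matches with score >= ``threshold`` and the
    spamogram of one-to-one selected matches *before* thresholding (so both
    the background and the homologous score peak remain visible).

    The pair is always compared with the lexicographically smaller taxon
    name as side 1, so results are symmetric in the argument order.
    """
    matrix = matrix or blosum62()
    swapped = prot2.taxon_name < prot1.taxon_name
    a, b = (prot2, prot1) if swapped else (prot1, prot2)

    ell = pattern_set.length
    enc1 = _EncodedProteome(a, ell)
    enc2 = _EncodedProteome(b, ell)
    spam = Spamogram()
    per_pattern: list[_PairMatches] = []

    for pi, pat in enumerate(pattern_set):
        off1, keys1 = _pattern_occurrences(enc1, pat)
        off2, keys2 = _pattern_occurrences(enc2, pat)
        sel = _match_pattern(enc1, enc2, off1, keys1, off2, keys2, pat, matrix, threshold, spam)
        sel.pattern_index = pi
        per_pattern.append(sel)

    if swapped:
        per_pattern = [
            _PairMatches(pm.pattern_index, pm.off2, pm.off1, pm.scores, pm.mismatches)
            for pm in per_pattern
        ]
        enc1, enc2 = enc2, enc1

    return MatchCollection(prot1, prot2, pattern_set, per_pattern, enc1, enc2), spam


def _match_pattern(
    enc1: _EncodedProteome,
    enc2: _EncodedProteome,
    off1: np.ndarray,
    keys1: np.ndarray,
    off2: np.ndarray,
    keys2: np.ndarray,
    pattern: Pattern,
    matrix: ScoringMatrix,
    threshold: int,
    spam: Spamogram,
) -> _PairMatches:
    """One-to-one selection for a single pattern (array pipeline)."""
    dc_pos = pattern.dontcare_positions
    tab = matrix.scores
    empty = np.zeros(0, dtype=np.int64)

    if keys1.size == 0 or keys2.size == 0:
        return _PairMatches(0, empty, empty.copy(), empty.copy(), empty.copy())

    u1, start1, cnt1 = np.unique(keys1, return_index=True, return_counts=True)
    u2, start2, cnt2 = np.unique(keys2, return_index=True, return_counts=True)
    common, i1, i2 = np.intersect1d(u1, u2, assume_unique=True, return_indices=True)
    if common.size == 0:
        return _PairMatches(0, empty, empty.copy(), empty.copy(), empty.copy())

    c1, c2 = cnt1[i1], cnt2[i2]
    s1, s2 = start1[i1], start2[i2]

    # fast path: unique-unique buckets need no greedy step
    singleton = (c1 == 1) & (c2 == 1)
    so1 = off1[s1[singleton]]
    so2 = off2[s2[singleton]]
    s_scores, s_mm = _score_candidates(enc1, enc2, so1, so2, dc_pos, tab)
    spam.add_scores(s_scores)
    keep = s_scores >= threshold
    acc_off1 = [so1[keep]]
    acc_off2 = [so2[keep]]
    acc_scores = [s_scores[keep]]
    acc_mm = [s_mm[keep]]

    # general buckets: n x n' candidates, greedy one-to-one per bucket
    for bi in np.flatnonzero(~singleton):
        b1 = off1[s1[bi] : s1[bi] + c1[bi]]
        b2 = off2[s2[bi] : s2[bi] + c2[bi]]
        co1 = np.repeat(b1, b2.size)
        co2 = np.tile(b2, b1.size)
        scores, mm = _score_candidates(enc1, enc2, co1, co2, dc_pos, tab)

        # spamogram: one-to-one selection without the threshold
        order_all = _candidate_order(scores, co1, co2)
        spam.add_scores(scores[_greedy_one_to_one(order_all, co1, co2)])

        # result: filter first, then select
        ok = scores >= threshold
        fo1, fo2, fsc, fmm = co1[ok], co2[ok], scores[ok], mm[ok]
        order = _candidate_order(fsc, fo1, fo2)
        sel = _greedy_one_to_one(order, fo1, fo2)
        acc_off1.append(fo1[sel])
        acc_off2.append(fo2[sel])
        acc_scores.append(fsc[sel])
        acc_mm.append(fmm[sel])

    return _PairMatches(
        0,
        np.concatenate(acc_off1),
        np.concatenate(acc_off2),
        np.concatenate(acc_scores),
        np.concatenate(acc_mm),
    )


def enumerate_candidates(
    prot1: Proteome,
    prot2: Proteome,
    pattern: Pattern,
    matrix: ScoringMatrix | None = None,
) -> list[SpacedWordMatch]:
    """All scored candidate matches under one pattern via the indexed
    pipeline, before threshold filtering and one-to-one selection.

    Materializes match objects; intended for inspection and validation on
    small inputs (use :func:`compare_proteomes` at scale).
    """
    matrix = matrix or blosum62()
    ell = pattern.length
    enc1 = _EncodedProteome(prot1, ell)
    enc2 = _EncodedProteome(prot2, ell)
    off1, keys1 = _pattern_occurrences(enc1, pattern)
    off2, keys2 = _pattern_occurrences(enc2, pattern)
    out: list[SpacedWordMatch] = []
    if keys1.size == 0 or keys2.size == 0:
        return out
    u1, start1, cnt1 = np.unique(keys1, return_index=True, return_counts=True)
    u2, start2, cnt2 = np.unique(keys2, return_index=True, return_counts=True)
    _, i1, i2 = np.intersect1d(u1, u2, assume_unique=True, return_indices=True)
    mp = pattern.match_positions
    for bi in range(i1.size):
        b1 = off1[start1[i1[bi]] : start1[i1[bi]] + cnt1[i1[bi]]]
        b2 = off2[start2[i2[bi]] : start2[i2[bi]] + cnt2[i2[bi]]]
        co1 = np.repeat(b1, b2.size)
        co2 = np.tile(b2, b1.size)
        scores, mm = _score_candidates(enc1, enc2, co1, co2, pattern.dontcare_positions, matrix.scores)
        s1, l1 = enc1.to_local(co1)
        s2, l2 = enc2.to_local(co2)
        for k in range(co1.size):
            w1 = prot1.sequences[int(s1[k])][int(l1[k]) : int(l1[k]) + ell]
            w2 = prot2.sequences[int(s2[k])][int(l2[k]) : int(l2[k]) + ell]
            key = "".join(w1[int(j)] for j in mp)
            out.append(
                SpacedWordMatch(
                    0,
                    SpacedWordOccurrence(int(s1[k]), int(l1[k]), key, w1),
                    SpacedWordOccurrence(int(s2[k]), int(l2[k]), key, w2),
                    int(scores[k]),
                    int(mm[k]),
                    ell - pattern.weight,
                )
            )
    return out


# ---------------------------------------------------------------------------
# brute-force reference enumerator (validation oracle for small inputs)
# ---------------------------------------------------------------------------


def enumerate_candidates_bruteforce(
    prot1: Proteome,
    prot2: Proteome,
    pattern: Pattern,
    matrix: ScoringMatrix | None = None,
) -> list[SpacedWordMatch]:
    """All candidate spaced-word matches by direct O(n * n' * ell) window
    comparison.  Reference implementation for validating the indexed
    pipeline on small inputs; do not use at scale."""
    matrix = matrix or blosum62()
    occs1 = extract_spaced_words(prot1, pattern)
    occs2 = extract_spaced_words(prot2, pattern)
    out = []
    for o1 in occs1:
        for o2 in occs2:
            if o1.key != o2.key:
                continue
            sc, mm = score_match(o1, o2, pattern, matrix)
            out.append(
                SpacedWordMatch(0, o1, o2, sc, mm, pattern.length - pattern.weight)
            )
    return out
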