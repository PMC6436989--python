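"""Spaced-word extraction, scoring, greedy one-to-one selection."""

from __future__ import annotations

import numpy as np
import pytest

from spacedist import (
    Pattern,
    PatternSet,
    Proteome,
    SpacedWordMatch,
    SpacedWordOccurrence,
    blosum62,
    compare_proteomes,
    enumerate_candidates,
    enumerate_candidates_bruteforce,
    extract_spaced_words,
    score_match,
    select_one_to_one,
)
from spacedist.proteome import AMINO_ACIDS

def single(name: str, seq: str) -> Proteome:
    return Proteome(name, (f"{name}_1",), (seq,))


class TestExtraction:
    def test_worked_example(self):
        """P=1100101 on ATNQRDAP: the spaced word TN**D*P occurs at 1-based
        position 2 (0-based offset 1)."""
        occs = extract_spaced_words(single("t", "ATNQRDAP"), Pattern("1100101"))
        assert [(o.offset, o.key) for o in occs] == [(0, "ATRA"), (1, "TNDP")]

    def test_all_match_pattern(self):
        occs = extract_spaced_words(single("t", "ACD"), Pattern("111"))
        assert len(occs) == 1
        assert occs[0].key == "ACD"

    def test_window_must_fit(self):
        assert extract_spaced_words(single("t", "ACDE"), Pattern("10101")) == []

    def test_windows_never_span_sequences(self):
        prot = Proteome("t", ("a", "b"), ("ACD", "EFG"))
        occs = extract_spaced_words(prot, Pattern("111"))
        assert {(o.seq_index, o.offset) for o in occs} == {(0, 0), (1, 0)}

    def test_ambiguous_windows_excluded(self):
        occs = extract_spaced_words(single("t", "ACXDE"), Pattern("11"))
        # windows at 1 and 2 contain X (at a match or don't-care position)
        assert [(o.offset, o.key) for o in occs] == [(0, "AC"), (3, "DE")]

    def test_sorted_by_key(self):
        occs = extract_spaced_words(single("t", "ABABAB".replace("B", "C")), Pattern("1"))
        keys = [o.key for o in occs]
        assert keys == sorted(keys)


class TestScoreMatch:
    def test_blosum62_dontcare_column(self):
        p = Pattern("101")
        o1 = extract_spaced_words(single("a", "ACD"), p)[0]
        o2 = extract_spaced_words(single("b", "AWD"), p)[0]
        assert score_match(o1, o2, p) == (-2, 1)  # BLOSUM62 C/W

    def test_identical_windows(self):
        p = Pattern("101")
        o = extract_spaced_words(single("a", "ACD"), p)[0]
        assert score_match(o, o, p) == (9, 0)  # BLOSUM62 C/C

    def test_all_match_pattern_scores_zero(self):
        p = Pattern("111")
        o = extract_spaced_words(single("a", "ACD"), p)[0]
        assert score_match(o, o, p) == (0, 0)

    def test_key_mismatch_is_an_error(self):
        p = Pattern("101")
        o1 = extract_spaced_words(single("a", "ACD"), p)[0]
        o2 = extract_spaced_words(single("b", "WCD"), p)[0]
        with pytest.raises(ValueError):
            score_match(o1, o2, p)


def _cand(score: int, i1: int, i2: int) -> SpacedWordMatch:
    o1 = SpacedWordOccurrence(0, i1, "K", "K")
    o2 = SpacedWordOccurrence(0, i2, "K", "K")
    return SpacedWordMatch(0, o1, o2, score, 0, 0)


class TestSelectOneToOne:
    def test_single_candidate_above_threshold(self):
        c = _cand(5, 0, 0)
        assert select_one_to_one([c], threshold=0) == [c]
        assert select_one_to_one([c], threshold=6) == []

    def test_two_against_one_takes_higher_score(self):
        cands = [_cand(5, 0, 0), _cand(7, 1, 0)]
        assert select_one_to_one(cands, threshold=0) == [_cand(7, 1, 0)]

    def test_two_by_two_greedy_trace(self):
        cands = [_cand(9, 0, 0), _cand(8, 0, 1), _cand(7, 1, 0), _cand(1, 1, 1)]
        assert select_one_to_one(cands, threshold=0) == [_cand(9, 0, 0), _cand(1, 1, 1)]

    def test_filter_before_matching(self):
        """A sub-threshold candidate must not block a homologous pair."""
        cands = [_cand(-5, 0, 0), _cand(3, 1, 0)]
        assert select_one_to_one(cands, threshold=0) == [_cand(3, 1, 0)]

    def test_result_is_a_matching(self):
        rng = np.random.default_rng(0)
        cands = [
            _cand(int(rng.integers(-10, 10)), int(rng.integers(5)), int(rng.integers(5)))
            for _ in range(40)
        ]
        sel = select_one_to_one(cands, threshold=-100)
        assert len({(c.occ1.seq_index, c.occ1.offset) for c in sel}) == len(sel)
        assert len({(c.occ2.seq_index, c.occ2.offset) for c in sel}) == len(sel)


@pytest.fixture(scope="module")
def small_pair():
    rng = np.random.default_rng(7)
    # low-complexity alphabet so spaced words recur and buckets get crowded
    sub = "ACDE"
    s1 = "".join(rng.choice(list(sub), 150))
    s2 = "".join(rng.choice(list(sub), 180))
    return single("p1", s1), single("p2", s2)


class TestCompareProteomes:
    def test_candidates_match_bruteforce(self, small_pair):
        p1, p2 = small_pair
        for bits in ("101", "1101", "10011"):
            pat = Pattern(bits)
            fast = enumerate_candidates(p1, p2, pat)
            brute = enumerate_candidates_bruteforce(p1, p2, pat)
            key = lambda m: (m.occ1.seq_index, m.occ1.offset, m.occ2.seq_index, m.occ2.offset)
            assert sorted(map(key, fast)) == sorted(map(key, brute))
            assert {key(m): (m.score, m.dontcare_mismatches) for m in fast} == {
                key(m): (m.score, m.dontcare_mismatches) for m in brute
            }

    def test_self_comparison_selects_every_window_at_max_score(self):
        seq = "".join(AMINO_ACIDS)  # repeat-free
        a, b = single("a", seq), single("b", seq)
        ps = PatternSet((Pattern("1011"),))
        mc, spam = compare_proteomes(a, b, ps, threshold=-1000)
        n_windows = len(seq) - 4 + 1
        assert len(mc) == n_windows
        scores = {m.score for m in mc}
        tab = blosum62()
        # the only don't-care column of 1011 is index 1; a self-match scores
        # the BLOSUM62 diagonal there, the maximum possible for that window
        expected = {tab.score(seq[i + 1], seq[i + 1]) for i in range(n_windows)}
        assert scores == expected
        assert spam.total == n_windows

    def test_disjoint_keys_give_no_matches(self):
        ps = PatternSet((Pattern("11"),))
        mc, spam = compare_proteomes(single("a", "AAAA"), single("b", "CCCC"), ps)
        assert len(mc) == 0
        assert spam == {}

    def test_symmetry_in_argument_order(self, small_pair):
        p1, p2 = small_pair
        ps = PatternSet((Pattern("1011"), Pattern("1101")))
        mc_ab, spam_ab = compare_proteomes(p1, p2, ps, threshold=-50)
        mc_ba, spam_ba = compare_proteomes(p2, p1, ps, threshold=-50)
        pairs_ab = sorted((m.score, m.dontcare_mismatches) for m in mc_ab)
        pairs_ba = sorted((m.score, m.dontcare_mismatches) for m in mc_ba)
        assert pairs_ab == pairs_ba
        assert spam_ab == spam_ba

    def test_monotonicity_in_threshold(self, small_pair):
        p1, p2 = small_pair
        ps = PatternSet((Pattern("1011"),))
        counts = [
            len(compare_proteomes(p1, p2, ps, threshold=t)[0])
            for t in (-20, -5, 0, 5, 20)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_one_to_one_within_each_pattern(self, small_pair):
        p1, p2 = small_pair
        ps = PatternSet((Pattern("1011"), Pattern("1101")))
        mc, _ = compare_proteomes(p1, p2, ps, threshold=-50)
        for pi in range(ps.m):
            sel = [m for m in mc if m.pattern_index == pi]
            assert len({(m.occ1.seq_index, m.occ1.offset) for m in sel}) == len(sel)
            assert len({(m.occ2.seq_index, m.occ2.offset) for m in sel}) == len(sel)

    def test_greedy_selection_against_bruteforce_greedy(self, small_pair):
        """The array pipeline's per-bucket greedy equals an object-level
        greedy over brute-force candidates."""
        p1, p2 = small_pair
        pat = Pattern("1011")
        T = 0
        brute = enumerate_candidates_bruteforce(p1, p2, pat)
        by_key: dict[str, list] = {}
        for m in brute:
            by_key.setdefault(m.occ1.key, []).append(m)
        expected = []
        for key in by_key:
            expected.extend(select_one_to_one(by_key[key], threshold=T))
        mc, _ = compare_proteomes(p1, p2, PatternSet((pat,)), threshold=T)
        k = lambda m: (m.occ1.offset, m.occ2.offset, m.score)
        assert sorted(map(k, mc)) == sorted(map(k, expected))
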