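"""Run-length FM-index: encoding, rank, LF, count, back-stepping, inversion."""

import numpy as np
import pytest

from pfpbwt import (
    FArray,
    RLFMIndex,
    SENTINEL_DOLLAR,
    backstep_sample,
    brute_bwt,
    brute_count,
    brute_suffix_array,
    from_display,
    invert_bwt,
    lf_map,
    run_length_encode,
)
from pfpbwt import demo
from pfpbwt.errors import InputError, InternalConsistencyError
from pfpbwt.synth import SynthConfig, synth_collection

WORKED_BWT = from_display(demo.BWT)


@pytest.fixture(scope="module")
def worked_rlbwt():
    return run_length_encode(WORKED_BWT)


@pytest.fixture(scope="module")
def worked_index():
    return RLFMIndex.from_bwt(WORKED_BWT)


class TestRunLengthEncode:
    def test_worked_example_run_decomposition(self, worked_rlbwt):
        heads = [chr(c) if c > 1 else "$" for c in worked_rlbwt.run_heads]
        lengths = list(worked_rlbwt.run_lengths)
        assert worked_rlbwt.r == 13
        assert heads == ["A", "T", "C", "G", "A", "!", "$", "!", "A", "T", "A", "T", "A"]
        assert lengths == [1, 6, 2, 4, 3, 1, 1, 1, 3, 1, 1, 1, 2]

    def test_uniform_and_alternating(self):
        assert run_length_encode(b"AAAA").r == 1
        assert run_length_encode(b"ABAB").r == 4

    def test_decode_is_inverse(self, worked_rlbwt):
        assert worked_rlbwt.decode() == WORKED_BWT


class TestRank:
    def test_rank_at_zero_is_zero(self, worked_rlbwt):
        for c in b"ACGT!":
            assert worked_rlbwt.rank(c, 0) == 0

    def test_rank_t_prefix_seven(self, worked_rlbwt):
        assert worked_rlbwt.rank(ord("T"), 7) == 6

    def test_rank_matches_naive_scan(self):
        rng = np.random.default_rng(17)
        bwt = bytes(rng.choice(np.frombuffer(b"ACGT", np.uint8), 500))
        index = run_length_encode(bwt)
        for _ in range(1000):
            c = int(rng.choice(np.frombuffer(b"ACGTN", np.uint8)))
            i = int(rng.integers(0, len(bwt) + 1))
            assert index.rank(c, i) == bwt[:i].count(c)

    def test_rank_at_full_length_is_histogram(self, worked_rlbwt):
        L = worked_rlbwt.length
        for c in set(WORKED_BWT):
            assert worked_rlbwt.rank(c, L) == WORKED_BWT.count(c)

    def test_out_of_range_raises(self, worked_rlbwt):
        with pytest.raises(InputError):
            worked_rlbwt.rank(ord("A"), worked_rlbwt.length + 1)
        with pytest.raises(InputError):
            worked_rlbwt.rank(ord("A"), -1)


class TestLFMap:
    def test_terminator_row_maps_to_zero(self, worked_index):
        # position 17 holds the terminator; C[$] = 0 and no $ precedes it
        assert WORKED_BWT[17] == SENTINEL_DOLLAR
        assert lf_map(worked_index.rlbwt, worked_index.F, 17) == 0

    def test_lf_is_a_single_cycle_permutation(self, worked_index):
        L = worked_index.rlbwt.length
        seen = set()
        cur = 0
        for _ in range(L):
            assert cur not in seen
            seen.add(cur)
            cur = lf_map(worked_index.rlbwt, worked_index.F, cur)
        assert cur == 0 and len(seen) == L

    def test_two_symbol_case(self):
        index = run_length_encode(b"A" + bytes([SENTINEL_DOLLAR]))
        F = FArray.from_rlbwt(index)
        assert lf_map(index, F, 0) == 1
        assert lf_map(index, F, 1) == 0

    def test_out_of_range_raises(self, worked_index):
        with pytest.raises(InputError):
            lf_map(worked_index.rlbwt, worked_index.F, worked_index.rlbwt.length)


class TestCount:
    @pytest.mark.parametrize("pattern, expected", [(b"GAT", 4), (b"ACAT", 2)])
    def test_worked_example_counts(self, worked_index, pattern, expected):
        assert worked_index.count(pattern) == brute_count(demo.TEXT, pattern)
        assert worked_index.count(pattern) == expected

    def test_absent_symbol_counts_zero(self, worked_index):
        assert worked_index.count(b"Z") == 0
        assert worked_index.count(b"GATZ") == 0

    def test_pattern_with_sentinel_rejected(self, worked_index):
        with pytest.raises(InputError):
            worked_index.count(b"GA\x01")

    def test_random_texts_match_naive_counting(self):
        rng = np.random.default_rng(29)
        for _ in range(5):
            text = bytes(rng.choice(np.frombuffer(b"ACG", np.uint8), 600))
            index = RLFMIndex.from_bwt(brute_bwt(text))
            for _ in range(200):
                m = int(rng.integers(1, 12))
                start = int(rng.integers(0, len(text) - m + 1))
                pattern = (
                    text[start:start + m]
                    if rng.random() < 0.7
                    else bytes(rng.choice(np.frombuffer(b"ACGT", np.uint8), m))
                )
                assert index.count(pattern) == brute_count(text, pattern)


class TestBackstepAndInvert:
    def test_two_symbol_samples_exhaustive(self):
        index = run_length_encode(b"A" + bytes([SENTINEL_DOLLAR]))
        sample = backstep_sample(index)
        assert sample.entries == [(0, 1), (1, 0)]

    def test_worked_example_samples_match_suffix_array(self, worked_rlbwt):
        sa = brute_suffix_array(demo.TEXT + bytes([SENTINEL_DOLLAR]))
        sample = backstep_sample(worked_rlbwt)
        assert sample.entries  # at least the run boundaries
        for bwt_pos, text_pos in sample.entries:
            assert sa[bwt_pos] == text_pos

    def test_random_texts_agree_at_every_run_boundary(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            text = bytes(rng.choice(np.frombuffer(b"AC", np.uint8), 300))
            bwt = brute_bwt(text)
            index = run_length_encode(bwt)
            sa = brute_suffix_array(text + bytes([SENTINEL_DOLLAR]))
            boundaries = set(index.run_boundaries())
            entries = dict(backstep_sample(index).entries)
            assert set(entries) == boundaries
            for pos in boundaries:
                assert entries[pos] == sa[pos]

    def test_invert_worked_example(self, worked_rlbwt):
        assert invert_bwt(worked_rlbwt) == demo.TEXT + bytes([SENTINEL_DOLLAR])

    def test_invert_round_trip_random(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            n = int(rng.integers(1, 400))
            text = bytes(rng.choice(np.frombuffer(b"ACGT", np.uint8), n))
            index = run_length_encode(brute_bwt(text))
            assert invert_bwt(index) == text + bytes([SENTINEL_DOLLAR])

    def test_malformed_bwt_rejected(self):
        # one terminator but not a valid BWT: the LF walk closes early
        with pytest.raises(InternalConsistencyError):
            invert_bwt(run_length_encode(bytes([SENTINEL_DOLLAR]) + b"AB"))
        # no terminator at all
        with pytest.raises(InternalConsistencyError):
            invert_bwt(run_length_encode(b"AB"))


def test_runs_grow_much_slower_than_text_on_repetitive_collections():
    """Adding near-identical copies multiplies the text length but barely
    moves the run count of its BWT."""
    def runs(copies: int) -> tuple[int, int]:
        cfg = SynthConfig(seed=9, base_length=2000, copies=copies,
                          mutation_rate=0.005)
        text = synth_collection(cfg)
        return run_length_encode(brute_bwt(text)).r, len(text)

    r1, n1 = runs(1)
    r8, n8 = runs(8)
    assert n8 == 8 * n1
    assert r8 / r1 < 2.5  # far below the 8x growth of the text
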