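import numpy as np
import pytest

from conftest import make_db
from lanesw.errors import ParameterError
from lanesw.fixtures import generate_overflow_case, generate_query
from lanesw.lane_engine import (
    BYTE_TIER,
    WORD_TIER,
    ChannelSet,
    EngineConfig,
    LaneBlockState,
    build_score_profile,
    detect_overflow,
    dump_state,
    lane_sweep,
    pad_to_block,
    process_block,
    saturated_cell_update,
    search_chunk,
)
from lanesw.reference_align import gotoh_column_sweep, gotoh_local_score
from lanesw.scoring import make_gap_penalties
from lanesw.sequences_io import EncodedSequence


class TestPadToBlock:
    @pytest.mark.parametrize(
        "length, B, pad", [(5, 4, 3), (8, 4, 0), (1, 4, 3), (0, 4, 0), (7, 1, 0)]
    )
    def test_padding_counts(self, length, B, pad):
        assert pad_to_block(length, B) == pad
        assert (length + pad) % B == 0

    def test_invalid_block(self):
        with pytest.raises(ParameterError):
            pad_to_block(5, 0)


class TestScoreProfile:
    def test_constant_block(self, blosum62):
        block = np.full((4, 16), 20, dtype=np.uint8)  # all W
        profile = build_score_profile(blosum62, block)
        assert profile.shape == (28, 4, 16)
        assert profile.shape[1] * profile.shape[2] == 64  # residues per rebuild
        table = blosum62.code_score_table()
        for c in range(28):
            assert (profile[c] == table[c, 20]).all()

    def test_random_blocks_match_direct_lookup(self, blosum62):
        rng = np.random.default_rng(3)
        table = blosum62.code_score_table()
        for _ in range(5):
            block = rng.integers(0, 28, size=(4, 16)).astype(np.uint8)
            profile = build_score_profile(blosum62, block)
            for c in range(28):
                for k in range(4):
                    for lane in range(16):
                        assert profile[c, k, lane] == table[c, block[k, lane]]

    def test_padding_scores_most_negative(self, blosum62):
        block = np.zeros((4, 8), dtype=np.uint8)
        profile = build_score_profile(blosum62, block)
        assert (profile == -128).all()


class TestSaturatedCellUpdate:
    def test_lower_saturation_is_the_zero_floor(self):
        bias = np.full(1, BYTE_TIER.bias, dtype=np.int64)
        h, e, f, s = saturated_cell_update(
            bias, np.array([-4]), bias.copy(), bias.copy(), bias.copy(), 12, 1, BYTE_TIER
        )
        assert h[0] == BYTE_TIER.bias  # raw 0 stays raw 0

    def test_single_path_arithmetic(self):
        b = BYTE_TIER.bias
        n = np.array([b + 10], dtype=np.int64)
        empty = np.array([b], dtype=np.int64)
        h, e, f, s = saturated_cell_update(
            n, np.array([5]), empty.copy(), empty.copy(), empty.copy(), 12, 1, BYTE_TIER
        )
        assert h[0] - b == 15
        assert s[0] - b == 15

    def test_upper_saturation_clamps(self):
        n = np.array([BYTE_TIER.stored_max], dtype=np.int64)
        b = np.array([BYTE_TIER.bias], dtype=np.int64)
        h, *_ = saturated_cell_update(
            n, np.array([11]), b.copy(), b.copy(), b.copy(), 12, 1, BYTE_TIER
        )
        assert h[0] == BYTE_TIER.stored_max


class TestProcessBlock:
    def test_columns_match_scalar_oracle(self, blosum62, gaps11_1):
        """Per-lane stored H/E columns equal the scalar sweep, column by column."""
        db = make_db(seed=31, n=3, lo=16, hi=16)
        query = generate_query(seed=32, length=12)
        q = query.residues
        for subject in db:
            state = LaneBlockState.new(q.size, lanes=1, block=4, tier=BYTE_TIER)
            oracle = gotoh_column_sweep(query, subject, blosum62, gaps11_1)
            for start in range(0, subject.length, 4):
                block = subject.residues[start : start + 4].reshape(4, 1)
                profile = build_score_profile(blosum62, block)
                process_block(state, profile, q, gaps11_1, query_unroll=2)
                for _ in range(4):
                    j, col = next(oracle)
                assert np.array_equal(state.Hcol[:, 0] - BYTE_TIER.bias, col.Hcol)
                assert np.array_equal(state.Ecol[:, 0] - BYTE_TIER.bias, col.Ecol)
                assert state.raw_best(0) == col.best

    def test_degenerate_geometry_reduces_to_scalar(self, blosum62, gaps11_1):
        db = make_db(seed=33, n=10, lo=1, hi=40)
        query = generate_query(seed=34, length=9)
        res = lane_sweep(
            query.residues, db.sequences, blosum62, gaps11_1, BYTE_TIER,
            lanes=1, block=1, query_unroll=1,
        )
        for r, s in zip(res, db):
            assert r.raw_score == gotoh_local_score(query, s, blosum62, gaps11_1)

    def test_stored_values_stay_in_tier_range(self, blosum62, gaps11_1):
        db = make_db(seed=35, n=8, lo=5, hi=50)
        query = generate_query(seed=36, length=20)
        q = query.residues
        state = LaneBlockState.new(q.size, lanes=4, block=4, tier=BYTE_TIER)
        channels = ChannelSet(lanes=4, block=4)
        from lanesw.lane_engine import _Channel, _padded

        for lane in range(4):
            ch = _Channel(lane, _padded(db[lane].residues, 4), 0)
            channels.channels[lane] = ch
        for _ in range(3):
            profile = build_score_profile(blosum62, channels.next_block())
            process_block(state, profile, q, gaps11_1, 2)
            channels.advance()
            for arr in (state.Hcol, state.Ecol, state.Fblock, state.Sbest):
                assert (arr >= BYTE_TIER.bias).all()
                assert (arr <= BYTE_TIER.stored_max).all()
        assert "tier=byte" in dump_state(state)


class TestGeometryInvariance:
    def test_scores_identical_across_geometries(self, blosum62, gaps11_1):
        db = make_db(seed=37, n=40, lo=1, hi=70, special_rate=0.02)
        query = generate_query(seed=38, length=33)
        reference = None
        for lanes in (1, 4, 16, 32):
            for block in (1, 4):
                for unroll in (1, 2):
                    res = search_chunk(
                        query, db.sequences, blosum62, gaps11_1,
                        EngineConfig(lanes=lanes, block=block, query_unroll=unroll),
                    )
                    scores = [r.score for r in res]
                    if reference is None:
                        reference = scores
                    assert scores == reference, (lanes, block, unroll)

    def test_order_invariance(self, blosum62, gaps11_1):
        db = make_db(seed=39, n=30, lo=1, hi=50)
        query = generate_query(seed=40, length=25)
        base = [r.score for r in search_chunk(query, db.sequences, blosum62, gaps11_1)]
        perm = np.random.default_rng(41).permutation(30)
        shuffled = [db.sequences[i] for i in perm]
        permuted = [r.score for r in search_chunk(query, shuffled, blosum62, gaps11_1)]
        assert permuted == [base[i] for i in perm]


class TestBoundaries:
    def test_multiple_sequences_share_and_leave_lanes(self, blosum62, gaps11_1):
        # more sequences than lanes: every lane is refilled several times
        db = make_db(seed=42, n=50, lo=1, hi=25)
        query = generate_query(seed=43, length=18)
        res = lane_sweep(
            query.residues, db.sequences, blosum62, gaps11_1, BYTE_TIER,
            lanes=4, block=4,
        )
        assert [r.ordinal for r in res] == list(range(50))
        for r, s in zip(res, db):
            assert r.raw_score == gotoh_local_score(query, s, blosum62, gaps11_1)


class TestOverflowAndEscalation:
    def test_small_scores_not_flagged(self, blosum62, gaps11_1, small_db, small_query):
        res = lane_sweep(
            small_query.residues, small_db.sequences, blosum62, gaps11_1, BYTE_TIER
        )
        for r, s in zip(res, small_db):
            exact = gotoh_local_score(small_query, s, blosum62, gaps11_1)
            if not r.flagged:
                assert r.raw_score == exact

    def test_byte_overflow_is_flagged_and_rescored(self, blosum62, gaps11_1):
        query, subject = generate_overflow_case(blosum62, gaps11_1, BYTE_TIER.capacity)
        exact = gotoh_local_score(query, subject, blosum62, gaps11_1)
        assert exact > BYTE_TIER.capacity
        res = search_chunk(query, [subject], blosum62, gaps11_1)
        assert res[0].score == exact
        assert res[0].tier == "word"
        assert res[0].escalated

    def test_word_overflow_escalates_to_exact(self, blosum62, gaps11_1):
        query, subject = generate_overflow_case(blosum62, gaps11_1, WORD_TIER.capacity)
        exact = gotoh_local_score(query, subject, blosum62, gaps11_1)
        assert exact > WORD_TIER.capacity
        res = search_chunk(query, [subject], blosum62, gaps11_1)
        assert res[0].score == exact
        assert res[0].tier == "exact"

    def test_detect_overflow_threshold(self, blosum62):
        state = LaneBlockState.new(4, lanes=2, block=4, tier=BYTE_TIER)
        state.Sbest[0] = BYTE_TIER.threshold(blosum62) - 1
        state.Sbest[1] = BYTE_TIER.threshold(blosum62)
        assert detect_overflow(state, blosum62).tolist() == [False, True]

    def test_mixed_chunk_with_one_hot_sequence(self, blosum62, gaps11_1):
        db = make_db(seed=44, n=20, lo=1, hi=40)
        _, hot = generate_overflow_case(blosum62, gaps11_1, BYTE_TIER.capacity)
        seqs = db.sequences[:10] + [hot] + db.sequences[10:]
        query = generate_query(seed=45, length=30)
        # make the query share the hot homopolymer so the hot subject overflows
        query = EncodedSequence.from_str(
            "hotq", hot.to_str()[:20] + query.to_str(), "hot prefix"
        )
        res = search_chunk(query, seqs, blosum62, gaps11_1)
        for r, s in zip(res, seqs):
            assert r.score == gotoh_local_score(query, s, blosum62, gaps11_1)
        assert res[10].tier in ("word", "exact")


def test_empty_query_rejected(blosum62, gaps11_1, small_db):
    with pytest.raises(ParameterError):
        search_chunk(
            EncodedSequence("q", []), small_db.sequences, blosum62, gaps11_1
        )


def test_empty_chunk_gives_empty_result(blosum62, gaps11_1, small_query):
    assert search_chunk(small_query, [], blosum62, gaps11_1) == []
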