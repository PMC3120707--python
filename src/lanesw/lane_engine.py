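"""Lane-parallel Smith-Waterman engine with saturated biased arithmetic.

Instead of aligning one database sequence at a time, residues from L
database sequences (default 16) occupy L parallel lanes and are all compared
against the same query residue at once; a lane is refilled with the next
database sequence, in file order, as soon as its current one ends.  Blocks
of B consecutive database positions (default 4) are processed per lane
before advancing to the next query row, and the inner loop is unrolled along
the query (default 2 rows), so each inner iteration covers a block of
``query_unroll x B`` cells per lane.

Scores are held in *biased stored form*: a raw score s is stored as
``s + bias`` and all additions/subtractions saturate at the tier bounds
``[bias, stored_max]`` - the lower clamp at the bias is exactly the local
alignment zero floor, and all maxima are plain maxima on stored values.  Two
narrow tiers exist: the byte tier (7-bit effective range, bias 128, stored
0..255) and the word tier (15-bit effective, bias 2^15, stored 0..2^16-1);
the exact tier is the unbounded scalar recurrence of
:mod:`lanesw.reference_align`.

A lane is flagged for potential overflow when its running best stored score
reaches ``stored_max - max_matrix_score``: any upper-bound clamp requires
the diagonal carry to exceed that threshold, so every corrupted score is
flagged (tier soundness), at the cost of occasionally rescoring a sequence
that was still exact.  Flagged sequences are rescored after the chunk
completes, first in the word tier (L/2 lanes), then exactly.

Sequences whose length is not a multiple of B are padded with 1..B-1 null
symbols (code 0, scoring -128 against everything), so a new sequence only
ever starts at a block boundary and end-of-sequence checks run once per
block instead of once per residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .errors import ParameterError
from .reference_align import gotoh_local_score
from .scoring import GapPenalties, ScoreMatrix
from .sequences_io import EncodedSequence

__all__ = [
    "Tier",
    "BYTE_TIER",
    "WORD_TIER",
    "EngineConfig",
    "LaneBlockState",
    "ChannelSet",
    "LaneScore",
    "pad_to_block",
    "build_score_profile",
    "saturated_cell_update",
    "process_block",
    "handle_boundaries",
    "detect_overflow",
    "lane_sweep",
    "search_chunk",
    "dump_state",
]


@dataclass(frozen=True)
class Tier:
    """A saturated narrow-integer precision level."""

    name: str
    bias: int
    stored_max: int

    @property
    def capacity(self) -> int:
        """Largest raw score representable without saturation."""
        return self.stored_max - self.bias

    def threshold(self, matrix: ScoreMatrix) -> int:
        """Stored-form overflow-flag threshold for ``matrix``."""
        return self.stored_max - matrix.max_score


BYTE_TIER = Tier("byte", 128, 255)
WORD_TIER = Tier("word", 1 << 15, (1 << 16) - 1)
TIERS = {"byte": BYTE_TIER, "word": WORD_TIER}


@dataclass(frozen=True)
class EngineConfig:
    """Lane-engine geometry.

    The defaults (16 lanes, blocks of 4 database positions, query unroll 2)
    reproduce the classic byte-vector geometry; results are identical for
    any geometry, only throughput differs.
    """

    lanes: int = 16
    block: int = 4
    query_unroll: int = 2
    tier: str = "byte"

    def __post_init__(self) -> None:
        if self.lanes < 1 or self.block < 1 or self.query_unroll < 1:
            raise ParameterError("lanes, block and query_unroll must all be >= 1")
        if self.tier not in TIERS:
            raise ParameterError(f"unknown tier {self.tier!r}")


def pad_to_block(length: int, B: int) -> int:
    """Number of null symbols needed to reach the next block boundary."""
    if B < 1:
        raise ParameterError(f"block length must be >= 1, got {B}")
    if length < 0:
        raise ParameterError(f"length must be >= 0, got {length}")
    return (B - length % B) % B


@dataclass
class LaneBlockState:
    """Per-lane engine state in biased stored form.

    ``Hcol``/``Ecol`` are (m+1, L) column arrays (H at the last processed
    column; E ready for the next column), ``Fblock`` the (B, L) running
    vertical-gap values inside the current block, ``Sbest`` the per-lane
    running maxima, and ``Ndiag`` the per-lane diagonal carry of the previous
    column's H, saved for the next cell on the diagonal.
    """

    Hcol: np.ndarray
    Ecol: np.ndarray
    Fblock: np.ndarray
    Sbest: np.ndarray
    Ndiag: np.ndarray
    tier: Tier

    @classmethod
    def new(cls, m: int, lanes: int, block: int, tier: Tier) -> "LaneBlockState":
        b = np.int64(tier.bias)
        return cls(
            Hcol=np.full((m + 1, lanes), b, dtype=np.int64),
            Ecol=np.full((m + 1, lanes), b, dtype=np.int64),
            Fblock=np.full((block, lanes), b, dtype=np.int64),
            Sbest=np.full(lanes, b, dtype=np.int64),
            Ndiag=np.full(lanes, b, dtype=np.int64),
            tier=tier,
        )

    def reset_lane(self, lane: int) -> None:
        """Reset one lane's H, E, F and S to raw zero (stored bias)."""
        b = self.tier.bias
        self.Hcol[:, lane] = b
        self.Ecol[:, lane] = b
        self.Fblock[:, lane] = b
        self.Sbest[lane] = b
        self.Ndiag[lane] = b

    def raw_best(self, lane: int) -> int:
        return int(self.Sbest[lane]) - self.tier.bias


def build_score_profile(
    matrix: ScoreMatrix, block_residues: np.ndarray
) -> np.ndarray:
    """Temporary score profile for one block of database residues.

    ``block_residues`` is a (B, L) array of residue codes (0 for padding).
    Returns an int16 array of shape (n_codes, B, L) whose entry
    ``[c, k, lane]`` is the substitution score of query code ``c`` against
    the residue at block position ``k`` of that lane - 64 database residues
    per rebuild at the default geometry.  Padding residues score the null
    symbol's most-negative value.
    """
    table = matrix.code_score_table()
    return table[:, np.asarray(block_residues, dtype=np.int64)]


def saturated_cell_update(
    n: np.ndarray,
    p: np.ndarray,
    e: np.ndarray,
    f: np.ndarray,
    s: np.ndarray,
    Q: int,
    R: int,
    tier: Tier,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One cell update on a vector of lanes, in stored form.

    ``n`` is the diagonal H carry, ``p`` the raw profile scores, ``e``/``f``
    the gap values ready for this cell and ``s`` the running best.  Returns
    ``(h, e_next, f_next, s)`` where ``e_next``/``f_next`` are ready for the
    next cell in the row/column respectively:

    H = max(sat_add(N, p), E, F);  S = max(S, H);
    E' = max(sat_sub(H, Q), sat_sub(E, R));
    F' = max(sat_sub(H, Q), sat_sub(F, R)).
    """
    lo, hi = tier.bias, tier.stored_max
    h = np.clip(np.asarray(n, dtype=np.int64) + p, lo, hi)
    h = np.maximum(h, np.maximum(e, f))
    s = np.maximum(s, h)
    hq = np.maximum(h - Q, lo)
    e_next = np.maximum(hq, np.maximum(e - R, lo))
    f_next = np.maximum(hq, np.maximum(f - R, lo))
    return h, e_next, f_next, s


@njit(cache=False, nogil=True)
def _block_kernel(
    Hcol, Ecol, Fblk, Sbest, Ndiag, profile, q, Q, R, bias, smax, unroll
):  # pragma: no cover - compiled
    m = q.shape[0]
    B = profile.shape[1]
    L = profile.shape[2]
    Hup = np.empty((B, L), dtype=np.int64)
    diag = np.empty(L, dtype=np.int64)
    erun = np.empty(L, dtype=np.int64)
    for k in range(B):
        for lane in range(L):
            Fblk[k, lane] = bias  # F never carries across block columns
            Hup[k, lane] = bias  # H row 0
    for lane in range(L):
        Ndiag[lane] = bias  # H[0][j0-1]
    i = 1
    while i <= m:
        top = min(i + unroll, m + 1)
        for r in range(i, top):
            c = q[r - 1]
            for lane in range(L):
                diag[lane] = Ndiag[lane]
                erun[lane] = Ecol[r, lane]
                Ndiag[lane] = Hcol[r, lane]  # pre-update H for next diagonal
            for k in range(B):
                for lane in range(L):
                    h = diag[lane] + profile[c, k, lane]
                    if h < bias:
                        h = bias
                    elif h > smax:
                        h = smax
                    e = erun[lane]
                    f = Fblk[k, lane]
                    if e > h:
                        h = e
                    if f > h:
                        h = f
                    if h > Sbest[lane]:
                        Sbest[lane] = h
                    hq = h - Q
                    if hq < bias:
                        hq = bias
                    en = e - R
                    if en < hq:
                        en = hq
                    erun[lane] = en
                    fn = f - R
                    if fn < hq:
                        fn = hq
                    Fblk[k, lane] = fn
                    diag[lane] = Hup[k, lane]
                    Hup[k, lane] = h
            for lane in range(L):
                Hcol[r, lane] = Hup[B - 1, lane]
                Ecol[r, lane] = erun[lane]
        i = top


def process_block(
    state: LaneBlockState,
    profile: np.ndarray,
    query_codes: np.ndarray,
    gaps: GapPenalties,
    query_unroll: int = 2,
) -> LaneBlockState:
    """Compute all m x B cells of the current block for every lane.

    Query rows are processed in groups of ``query_unroll``, each row covering
    the B database positions of the block before the next row starts (the
    default geometry computes eight cells per inner iteration).  The result
    is contract-equal to B successive single-column updates; the block shape
    only changes memory traffic, never scores.
    """
    _block_kernel(
        state.Hcol,
        state.Ecol,
        state.Fblock,
        state.Sbest,
        state.Ndiag,
        np.ascontiguousarray(profile),
        np.asarray(query_codes, dtype=np.uint8),
        np.int64(gaps.Q),
        np.int64(gaps.R),
        np.int64(state.tier.bias),
        np.int64(state.tier.stored_max),
        np.int64(query_unroll),
    )
    return state


def detect_overflow(state: LaneBlockState, matrix: ScoreMatrix) -> np.ndarray:
    """Per-lane potential-overflow flags (conservative, sticky by monotony).

    A lane is flagged when its stored best reaches
    ``stored_max - max_score``: any saturating addition implies the diagonal
    carry already exceeded this bound, so no silently wrong score can stay
    unflagged; scores strictly below the threshold are exact.
    """
    return state.Sbest >= state.tier.threshold(matrix)


@dataclass
class _Channel:
    """One lane's occupancy: the sequence, its padded residues and a cursor."""

    ordinal: Optional[int] = None  # index within the chunk
    residues: Optional[np.ndarray] = None  # padded to a block multiple
    cursor: int = 0

    @property
    def empty(self) -> bool:
        return self.ordinal is None

    @property
    def ended(self) -> bool:
        return (not self.empty) and self.cursor >= len(self.residues)


@dataclass
class ChannelSet:
    """Assignment of chunk sequences to lanes, refilled in file order."""

    lanes: int
    block: int
    channels: List[_Channel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.channels:
            self.channels = [_Channel() for _ in range(self.lanes)]

    def next_block(self) -> np.ndarray:
        """(B, L) residue codes for the next block column; 0 pads empty lanes."""
        out = np.zeros((self.block, self.lanes), dtype=np.uint8)
        for lane, ch in enumerate(self.channels):
            if not ch.empty:
                out[:, lane] = ch.residues[ch.cursor : ch.cursor + self.block]
        return out

    def advance(self) -> None:
        for ch in self.channels:
            if not ch.empty:
                ch.cursor += self.block


@dataclass(frozen=True)
class LaneScore:
    """Score of one database sequence as produced by a narrow-tier sweep."""

    ordinal: int
    raw_score: int
    flagged: bool


def handle_boundaries(
    channels: ChannelSet,
    state: LaneBlockState,
    queue: Iterator[Tuple[int, np.ndarray]],
    matrix: ScoreMatrix,
) -> List[LaneScore]:
    """Record scores of lanes whose sequence ended and refill them.

    Called once per block boundary.  When no lane ended this is a fast
    no-change path.  For each ended lane the (ordinal, score, overflow flag)
    triple is emitted, the lane's H/E/F/S state is reset to raw zero, and the
    next queued sequence (already block-padded) is loaded - or the lane is
    marked empty when the chunk is exhausted.
    """
    if not any(ch.ended for ch in channels.channels):
        return []
    emitted: List[LaneScore] = []
    threshold = state.tier.threshold(matrix)
    for lane, ch in enumerate(channels.channels):
        while ch.ended:
            emitted.append(
                LaneScore(
                    ordinal=ch.ordinal,
                    raw_score=state.raw_best(lane),
                    flagged=bool(state.Sbest[lane] >= threshold),
                )
            )
            state.reset_lane(lane)
            nxt = next(queue, None)
            if nxt is None:
                channels.channels[lane] = _Channel()
                break
            ordinal, padded = nxt
            ch = _Channel(ordinal, padded, 0)
            channels.channels[lane] = ch
    return emitted


def _padded(residues: np.ndarray, B: int) -> np.ndarray:
    pad = pad_to_block(residues.size, B)
    if pad == 0:
        return residues
    return np.concatenate([residues, np.zeros(pad, dtype=np.uint8)])


def lane_sweep(
    query_codes: np.ndarray,
    sequences: Sequence[EncodedSequence],
    matrix: ScoreMatrix,
    gaps: GapPenalties,
    tier: Tier,
    lanes: int = 16,
    block: int = 4,
    query_unroll: int = 2,
) -> List[LaneScore]:
    """Score every sequence in one narrow tier; results in chunk order.

    This is the full channelled sweep: sequences are fed to lanes in file
    order, blocks are processed across all lanes, and boundary handling
    emits scores and refills lanes.  Raw scores of unflagged sequences are
    exact; flagged ones must be rescored in a wider tier.
    """
    m = query_codes.size
    queue = iter(
        (i, _padded(np.asarray(s.residues, dtype=np.uint8), block))
        for i, s in enumerate(sequences)
    )
    channels = ChannelSet(lanes=lanes, block=block)
    state = LaneBlockState.new(m, lanes, block, tier)
    results: List[LaneScore] = []
    # Initial fill, in file order.
    for lane in range(lanes):
        nxt = next(queue, None)
        if nxt is None:
            break
        channels.channels[lane] = _Channel(nxt[0], nxt[1], 0)
    # Zero-length sequences terminate immediately; flush them up front.
    results.extend(handle_boundaries(channels, state, queue, matrix))
    while any(not ch.empty for ch in channels.channels):
        profile = build_score_profile(matrix, channels.next_block())
        process_block(state, profile, query_codes, gaps, query_unroll)
        channels.advance()
        results.extend(handle_boundaries(channels, state, queue, matrix))
    results.sort(key=lambda r: r.ordinal)
    return results


@dataclass(frozen=True)
class ChunkScore:
    """Final exact score of one chunk sequence with tier provenance."""

    ordinal: int
    score: int
    tier: str
    escalated: bool


def search_chunk(
    query: EncodedSequence,
    chunk: Sequence[EncodedSequence],
    matrix: ScoreMatrix,
    gaps: GapPenalties,
    config: EngineConfig = EngineConfig(),
) -> List[ChunkScore]:
    """Exact scores for every chunk sequence, escalating tiers as needed.

    The whole chunk first runs through the byte-tier lane engine; sequences
    flagged for potential overflow are then rescored with the word tier at
    half the lane count, and any still-flagged survivors with the exact
    scalar recurrence.  Every returned score equals the optimal local
    alignment score.
    """
    if query.length == 0:
        raise ParameterError("query must be nonempty")
    seqs = list(chunk)
    if not seqs:
        return []
    q = np.asarray(query.residues, dtype=np.uint8)
    first = lane_sweep(
        q, seqs, matrix, gaps, TIERS[config.tier],
        config.lanes, config.block, config.query_unroll,
    )
    out: dict[int, ChunkScore] = {}
    flagged = []
    for r in first:
        if r.flagged:
            flagged.append(r.ordinal)
        else:
            out[r.ordinal] = ChunkScore(r.ordinal, r.raw_score, config.tier, False)
    if flagged and config.tier == "byte":
        word = lane_sweep(
            q, [seqs[i] for i in flagged], matrix, gaps, WORD_TIER,
            max(1, config.lanes // 2), config.block, config.query_unroll,
        )
        still = []
        for r in word:
            ordinal = flagged[r.ordinal]
            if r.flagged:
                still.append(ordinal)
            else:
                out[ordinal] = ChunkScore(ordinal, r.raw_score, "word", True)
        flagged = still
    for ordinal in flagged:
        exact = gotoh_local_score(query, seqs[ordinal], matrix, gaps)
        out[ordinal] = ChunkScore(ordinal, exact, "exact", True)
    return [out[i] for i in range(len(seqs))]


def dump_state(state: LaneBlockState) -> str:
    """Debug dump of the stored-form lane columns as tab-separated text.

    One line per query row: ``H <i> <L stored values>`` then the same for E,
    followed by single lines for F (flattened block), S and N.
    """
    lines = [f"# tier={state.tier.name} bias={state.tier.bias}"]
    for label, arr in (("H", state.Hcol), ("E", state.Ecol)):
        for i in range(arr.shape[0]):
            lines.append(f"{label}\t{i}\t" + "\t".join(str(int(v)) for v in arr[i]))
    lines.append("F\t-\t" + "\t".join(str(int(v)) for v in state.Fblock.ravel()))
    lines.append("S\t-\t" + "\t".join(str(int(v)) for v in state.Sbest))
    lines.append("N\t-\t" + "\t".join(str(int(v)) for v in state.Ndiag))
    return "\n".join(lines) + "\n"
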