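"""Exact scalar Smith-Waterman/Gotoh local alignment score.

This is the widest tier of the precision ladder (unbounded integers, no
saturation) and the correctness oracle for the lane engine.  The recurrence
over query ``q`` (length m) and database sequence ``d`` (length n) with
substitution scores ``P`` and affine penalties ``Q = open + extend``,
``R = extend`` is::

    H[i][j] = max(0, H[i-1][j-1] + P[q_i, d_j], E[i][j], F[i][j])
    E[i][j] = max(H[i][j-1] - Q, E[i][j-1] - R)   # gap in the query
    F[i][j] = max(H[i-1][j] - Q, F[i-1][j] - R)   # gap in the database
    S       = max over i, j of H[i][j]

with zero boundaries.  The computation proceeds column by column over the
database sequence and keeps only one H column, one E column and a running F
element in memory (O(m) space).  E and F are floored at zero, which never
changes H or S because H already takes a maximum with zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Tuple

import numpy as np
from numba import njit

from .scoring import GapPenalties, ScoreMatrix
from .sequences_io import EncodedSequence

__all__ = ["ColumnState", "gotoh_local_score", "gotoh_column_sweep"]


@dataclass
class ColumnState:
    """One column of the Gotoh sweep (exposed for column-level testing).

    ``Hcol[i]`` / ``Ecol[i]`` hold, after processing column j, the H value at
    (i, j) and the E value ready for column j+1; ``best`` is the running
    optimum S.
    """

    Hcol: np.ndarray
    Ecol: np.ndarray
    F: int = 0
    best: int = 0

    @classmethod
    def new(cls, m: int) -> "ColumnState":
        return cls(np.zeros(m + 1, dtype=np.int64), np.zeros(m + 1, dtype=np.int64))


@njit(cache=False, nogil=True)
def _gotoh_kernel(q, d, table, Q, R):  # pragma: no cover - compiled
    m = q.shape[0]
    n = d.shape[0]
    Hcol = np.zeros(m + 1, dtype=np.int64)
    Ecol = np.zeros(m + 1, dtype=np.int64)
    best = 0
    for j in range(1, n + 1):
        dj = d[j - 1]
        f = 0
        hdiag = 0  # H[i-1][j-1]
        for i in range(1, m + 1):
            h = hdiag + table[q[i - 1], dj]
            e = Ecol[i]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            if h > best:
                best = h
            hdiag = Hcol[i]
            Hcol[i] = h
            hq = h - Q
            en = e - R
            if en < hq:
                en = hq
            if en < 0:
                en = 0
            Ecol[i] = en
            fn = f - R
            if fn < hq:
                fn = hq
            if fn < 0:
                fn = 0
            f = fn
    return best


def gotoh_local_score(
    query: EncodedSequence,
    subject: EncodedSequence,
    matrix: ScoreMatrix,
    gaps: GapPenalties,
) -> int:
    """Exact optimal local alignment score of ``query`` vs ``subject``.

    Returns a non-negative integer; either sequence being empty gives 0.
    """
    q = np.asarray(query.residues, dtype=np.uint8)
    d = np.asarray(subject.residues, dtype=np.uint8)
    if q.size == 0 or d.size == 0:
        return 0
    table = matrix.code_score_table()
    return int(_gotoh_kernel(q, d, table, np.int64(gaps.Q), np.int64(gaps.R)))


def gotoh_column_sweep(
    query: EncodedSequence,
    subject: EncodedSequence,
    matrix: ScoreMatrix,
    gaps: GapPenalties,
) -> Iterator[Tuple[int, ColumnState]]:
    """Yield ``(j, state)`` after each database column (pure Python).

    Slow but transparent; used to compare per-lane engine columns against the
    scalar recurrence cell by cell.
    """
    table = matrix.code_score_table()
    q = query.residues
    m = q.size
    state = ColumnState.new(m)
    Q, R = gaps.Q, gaps.R
    for j, dj in enumerate(subject.residues, start=1):
        f = 0
        hdiag = 0
        for i in range(1, m + 1):
            h = max(hdiag + int(table[q[i - 1], dj]), int(state.Ecol[i]), f, 0)
            state.best = max(state.best, h)
            hdiag = int(state.Hcol[i])
            state.Hcol[i] = h
            state.Ecol[i] = max(h - Q, int(state.Ecol[i]) - R, 0)
            f = max(h - Q, f - R, 0)
        state.F = f
        yield j, state
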