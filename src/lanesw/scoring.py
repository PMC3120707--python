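"""Substitution score matrices and affine gap penalties.

Matrices are parsed from the NCBI text layout ('#' comments, a header row of
symbols, one labelled row per symbol) and held as plain integer arrays; all
scoring in this package is integer-exact, with no floating point anywhere.

A code-indexed lookup table bridges the matrix alphabet and the residue byte
codes of :mod:`lanesw.sequences_io`.  The null/padding symbol (code 0) is
assigned the most negative representable score (-128) against everything, so
padding can never start or extend a local alignment.  Residue letters absent
from a matrix alphabet (e.g. J/O/U with older matrices) fall back to a
configurable symbol, 'X' by default, or to the matrix minimum when even the
fallback is missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .errors import MatrixParseError, ParameterError
from .sequences_io import CODE_OF, MAX_CODE

__all__ = [
    "NULL_SCORE",
    "BUILTIN_MATRICES",
    "ScoreMatrix",
    "GapPenalties",
    "parse_score_matrix",
    "load_matrix",
    "make_gap_penalties",
]

#: Score of the null/padding symbol (code 0) against any symbol.
NULL_SCORE = -128

#: Names of the matrices bundled as package data.
BUILTIN_MATRICES = (
    "BLOSUM45",
    "BLOSUM50",
    "BLOSUM62",
    "BLOSUM80",
    "BLOSUM90",
    "PAM30",
    "PAM70",
    "PAM250",
)


class ScoreMatrix:
    """A symmetric integer substitution matrix over a residue alphabet.

    Parameters
    ----------
    name : str
        Label, e.g. ``"BLOSUM62"``.
    alphabet : str
        Ordered residue symbols (letters plus optional ambiguity symbols).
    scores : numpy.ndarray
        Square integer array, ``scores[i, j]`` being the score of aligning
        ``alphabet[i]`` with ``alphabet[j]`` (log-odds units).
    """

    def __init__(self, name: str, alphabet: str, scores: np.ndarray):
        scores = np.asarray(scores, dtype=np.int16)
        if scores.ndim != 2 or scores.shape[0] != scores.shape[1]:
            raise MatrixParseError(f"{name}: score table is not square")
        if scores.shape[0] != len(alphabet):
            raise MatrixParseError(
                f"{name}: {len(alphabet)} symbols but {scores.shape[0]} rows"
            )
        if len(set(alphabet)) != len(alphabet):
            raise MatrixParseError(f"{name}: duplicate symbols in alphabet")
        if not np.array_equal(scores, scores.T):
            a, b = map(int, np.argwhere(scores != scores.T)[0])
            raise MatrixParseError(
                f"{name}: asymmetric entries at {alphabet[a]!r}/{alphabet[b]!r}"
            )
        if scores.min() < -128 or scores.max() > 127:
            raise MatrixParseError(f"{name}: scores outside signed 8-bit range")
        self.name = name
        self.alphabet = alphabet
        self.scores = scores
        self.min_score = int(scores.min())
        self.max_score = int(scores.max())
        self._index = {sym: i for i, sym in enumerate(alphabet)}
        self._code_table: Optional[np.ndarray] = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ScoreMatrix({self.name!r}, {len(self.alphabet)} symbols)"

    def score(self, a: str, b: str) -> int:
        """Score of aligning symbols ``a`` and ``b``."""
        try:
            return int(self.scores[self._index[a.upper()], self._index[b.upper()]])
        except KeyError as exc:
            raise ParameterError(
                f"symbol {exc.args[0]!r} not in {self.name} alphabet"
            ) from None

    def drop_symbol(self, symbol: str) -> "ScoreMatrix":
        """Return a copy with ``symbol``'s row and column removed."""
        if symbol not in self._index:
            return self
        keep = [i for i, s in enumerate(self.alphabet) if s != symbol]
        return ScoreMatrix(
            self.name,
            "".join(self.alphabet[i] for i in keep),
            self.scores[np.ix_(keep, keep)],
        )

    def code_score_table(self, fallback: str = "X") -> np.ndarray:
        """(MAX_CODE+1)² int16 table indexed by residue byte codes.

        Row/column 0 (the null symbol) and any code whose letter is absent
        from the alphabet when no ``fallback`` exists hold :data:`NULL_SCORE`
        or the matrix minimum respectively, so the engine can index the table
        directly with encoded residues.
        """
        if self._code_table is not None and fallback == "X":
            return self._code_table
        n = MAX_CODE + 1
        table = np.full((n, n), NULL_SCORE, dtype=np.int16)
        fb = self._index.get(fallback)
        col_of_code: dict[int, Optional[int]] = {}
        for letter, code in CODE_OF.items():
            idx = self._index.get(letter, fb)
            col_of_code[code] = idx
        for c1, i1 in col_of_code.items():
            for c2, i2 in col_of_code.items():
                if i1 is None or i2 is None:
                    table[c1, c2] = self.min_score
                else:
                    table[c1, c2] = self.scores[i1, i2]
        # Null symbol overrides everything.
        table[0, :] = NULL_SCORE
        table[:, 0] = NULL_SCORE
        if fallback == "X":
            self._code_table = table
        return table

    def to_text(self) -> str:
        """Serialise in the NCBI text layout (round-trips through the parser)."""
        lines = [f"# {self.name} substitution matrix"]
        lines.append("   " + "  ".join(self.alphabet))
        for i, sym in enumerate(self.alphabet):
            row = " ".join(f"{int(v):3d}" for v in self.scores[i])
            lines.append(f"{sym} {row}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap penalties: a gap of length k costs Q + (k-1)*R.

    ``open`` is the penalty for opening a gap and ``extend`` the penalty per
    gap position; the derived per-gap quantities are ``Q = open + extend``
    and ``R = extend``.
    """

    open: int
    extend: int

    def __post_init__(self) -> None:
        if self.extend < 1:
            raise ParameterError(f"gap extend must be >= 1, got {self.extend}")
        if self.open < 0:
            raise ParameterError(f"gap open must be >= 0, got {self.open}")

    @property
    def Q(self) -> int:
        return self.open + self.extend

    @property
    def R(self) -> int:
        return self.extend


def make_gap_penalties(open: int, extend: int) -> GapPenalties:
    """Validate and build :class:`GapPenalties` (open >= 0, extend >= 1)."""
    return GapPenalties(int(open), int(extend))


def parse_score_matrix(
    text: str, *, name: str = "custom", drop_stop: bool = False
) -> ScoreMatrix:
    """Parse an NCBI-format score matrix from ``text``.

    Lines starting with ``#`` are comments.  The first data line is the
    header row of symbols; each following line is a symbol label and its
    scores.  When ``drop_stop`` is set, the stop-codon symbol ``'*'`` row and
    column are removed after parsing.

    Raises
    ------
    MatrixParseError
        On a non-square table, asymmetric entries, an unknown or out-of-order
        row label, or a value outside [-128, 127], naming the offender.
    """
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise MatrixParseError(f"{name}: no data lines")
    header = lines[0].split()
    alphabet = "".join(header)
    size = len(header)
    scores = np.zeros((size, size), dtype=np.int64)
    rows = lines[1:]
    if len(rows) != size:
        raise MatrixParseError(
            f"{name}: header has {size} symbols but found {len(rows)} rows"
        )
    seen = []
    for row_line in rows:
        fields = row_line.split()
        label = fields[0]
        if label not in header:
            raise MatrixParseError(f"{name}: unknown row label {label!r}")
        if len(fields) - 1 != size:
            raise MatrixParseError(
                f"{name}: row {label!r} has {len(fields) - 1} values, expected {size}"
            )
        i = header.index(label)
        for j, val_s in enumerate(fields[1:]):
            try:
                val = int(val_s)
            except ValueError as exc:
                raise MatrixParseError(
                    f"{name}: row {label!r}, column {header[j]!r}: "
                    f"non-integer value {val_s!r}"
                ) from exc
            if not -128 <= val <= 127:
                raise MatrixParseError(
                    f"{name}: row {label!r}, column {header[j]!r}: "
                    f"value {val} outside [-128, 127]"
                )
            scores[i, j] = val
        seen.append(label)
    if len(set(seen)) != size:
        raise MatrixParseError(f"{name}: duplicate row labels")
    matrix = ScoreMatrix(name, alphabet, scores)
    if drop_stop:
        matrix = matrix.drop_symbol("*")
    return matrix


def load_matrix(name: str, *, drop_stop: bool = True) -> ScoreMatrix:
    """Load a bundled matrix by name (see :data:`BUILTIN_MATRICES`).

    The stop-codon row/column is removed by default, matching common practice
    for tools whose encodings carry no stop symbol.
    """
    key = name.upper()
    if key not in BUILTIN_MATRICES:
        raise ParameterError(
            f"unknown matrix {name!r}; bundled matrices: {', '.join(BUILTIN_MATRICES)}"
        )
    text = (
        resources.files("lanesw.matrices").joinpath(f"{key}.txt").read_text()
    )
    return parse_score_matrix(text, name=key, drop_stop=drop_stop)
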