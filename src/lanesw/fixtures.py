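"""Deterministic synthetic protein data for testing and benchmarking.

Everything here is reproducible from a seed: random databases with a
configurable length law and residue composition, adversarial pairs that
force precision-tier escalation, and a small frozen worked example.  The
default database spec - 2,000 sequences with a long-tailed (discretised
gamma) length law of mean 350 - is a desk-scale stand-in for a real protein
knowledgebase: large enough to exercise lane refilling, chunking and tier
escalation, while completing in seconds.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np

from .errors import ParameterError
from .reference_align import gotoh_local_score
from .scoring import GapPenalties, ScoreMatrix, load_matrix, make_gap_penalties
from .sequences_io import EncodedSequence, SequenceDatabase, read_fasta_db

__all__ = [
    "STANDARD_RESIDUES",
    "FixtureSpec",
    "blosum_background",
    "generate_database",
    "write_fixture",
    "generate_overflow_case",
    "worked_example",
    "WORKED_EXAMPLE_SCORES",
]

#: The 20 standard amino acids, in the residue-code encoding order.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Special residues inserted at ``special_symbol_rate``.
SPECIAL_RESIDUES = "JOUX"

# Robinson & Robinson style background frequencies over STANDARD_RESIDUES,
# used when a BLOSUM-like composition is requested instead of uniform.
_BLOSUM_BG = {
    "A": 0.078, "C": 0.019, "D": 0.054, "E": 0.063, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.051, "K": 0.057, "L": 0.091,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.071, "T": 0.058, "V": 0.064, "W": 0.013, "Y": 0.032,
}


def blosum_background() -> np.ndarray:
    """Normalised BLOSUM-style background composition over the 20 residues."""
    freqs = np.array([_BLOSUM_BG[r] for r in STANDARD_RESIDUES], dtype=float)
    return freqs / freqs.sum()


LengthLaw = Union[
    Tuple[str, float, float],  # ("uniform", a, b) or ("gamma", shape, scale)
    Tuple[str, List[int]],  # ("fixed", [lengths...])
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible synthetic database.

    ``length_law`` is ``("uniform", a, b)`` (inclusive integer bounds),
    ``("gamma", shape, scale)`` (discretised, floored at 1), or
    ``("fixed", [lengths])``.  ``composition`` is a frequency vector over the
    20 standard amino acids (uniform by default).  ``special_symbol_rate``
    is the per-position probability of replacing a residue with one of
    J/O/U/X.
    """

    seed: int
    n_sequences: int = 2000
    length_law: LengthLaw = ("gamma", 2.0, 175.0)
    composition: Optional[np.ndarray] = None
    special_symbol_rate: float = 0.0

    def normalised_composition(self) -> np.ndarray:
        if self.composition is None:
            return np.full(20, 1 / 20)
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (20,) or (comp < 0).any():
            raise ParameterError("composition must be 20 non-negative frequencies")
        total = comp.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ParameterError(f"composition must sum to 1, got {total:.6f}")
        return comp / total


def _draw_lengths(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    law = spec.length_law
    kind = law[0]
    if kind == "uniform":
        a, b = int(law[1]), int(law[2])
        if a < 1 or b < a:
            raise ParameterError(f"bad uniform length bounds ({a}, {b})")
        return rng.integers(a, b + 1, size=spec.n_sequences)
    if kind == "gamma":
        shape, scale = float(law[1]), float(law[2])
        if shape <= 0 or scale <= 0:
            raise ParameterError("gamma shape and scale must be positive")
        return np.maximum(1, rng.gamma(shape, scale, size=spec.n_sequences).round().astype(int))
    if kind == "fixed":
        lengths = np.asarray(law[1], dtype=int)
        if lengths.size != spec.n_sequences:
            raise ParameterError("fixed length list does not match n_sequences")
        return lengths
    raise ParameterError(f"unknown length law {kind!r}")


def generate_database(spec: FixtureSpec) -> str:
    """Render a synthetic database as FASTA text (byte-reproducible)."""
    rng = np.random.default_rng(spec.seed)
    comp = spec.normalised_composition()
    lengths = _draw_lengths(spec, rng)
    residues = np.array(list(STANDARD_RESIDUES))
    specials = np.array(list(SPECIAL_RESIDUES))
    records = []
    for i, length in enumerate(lengths):
        letters = rng.choice(residues, size=length, p=comp)
        if spec.special_symbol_rate > 0:
            mask = rng.random(length) < spec.special_symbol_rate
            if mask.any():
                letters[mask] = rng.choice(specials, size=int(mask.sum()))
        seq = "".join(letters)
        records.append(f">syn{i + 1:06d} synthetic length={length}\n")
        for start in range(0, len(seq), 60):
            records.append(seq[start : start + 60] + "\n")
    return "".join(records)


def generate_query(seed: int, length: int = 375) -> EncodedSequence:
    """One synthetic query sequence of typical protein length."""
    spec = FixtureSpec(seed=seed, n_sequences=1, length_law=("fixed", [length]))
    db = read_fasta_db(_as_stream(generate_database(spec)))
    seq = db[0]
    return EncodedSequence("query001", seq.residues, f"synthetic query length={length}")


def _as_stream(text: str):
    import io

    return io.StringIO(text)


def write_fixture(spec: FixtureSpec, path: Union[str, os.PathLike]) -> SequenceDatabase:
    """Write ``<path>.fasta`` plus a ``<path>.manifest.json`` sidecar.

    The manifest records the spec and a SHA-256 checksum so a fixture can be
    regenerated and verified byte for byte.
    """
    text = generate_database(spec)
    base = os.fspath(path)
    with open(base + ".fasta", "w") as fh:
        fh.write(text)
    manifest = {
        "seed": spec.seed,
        "n_sequences": spec.n_sequences,
        "length_law": list(spec.length_law),
        "special_symbol_rate": spec.special_symbol_rate,
        "sha256": hashlib.sha256(text.encode()).hexdigest(),
    }
    with open(base + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=list)
    return read_fasta_db(_as_stream(text))


def generate_overflow_case(
    matrix: ScoreMatrix, gaps: GapPenalties, tier_capacity: int
) -> Tuple[EncodedSequence, EncodedSequence]:
    """A (query, subject) pair whose exact score exceeds ``tier_capacity``.

    The pair is a homopolymer repeat of the matrix's best-scoring diagonal
    residue, long enough that the self-alignment score passes the capacity;
    the construction is verified against the scalar oracle before returning.

    Raises
    ------
    ParameterError
        If the matrix has no positive diagonal entry (no repeat of a single
        residue can then accumulate a positive score).
    """
    diag = np.diag(matrix.scores)
    best = int(diag.max())
    if best <= 0:
        raise ParameterError(f"{matrix.name}: no positive diagonal entry")
    letter = matrix.alphabet[int(diag.argmax())]
    n = tier_capacity // best + 2
    while True:
        seq = EncodedSequence.from_str("overflow", letter * n, f"{letter}x{n}")
        score = gotoh_local_score(seq, seq, matrix, gaps)
        if score > tier_capacity:
            return seq, seq
        n *= 2


# Frozen worked example: a 12-residue query against five hand-picked
# subjects.  Expected scores were computed by the scalar oracle
# (scripts/regen_worked_example.py regenerates and checks this table).
_WE_QUERY = ("toyq", "MKWVLAHTGERC", "worked-example query")
_WE_SUBJECTS = [
    ("identical", "MKWVLAHTGERC", "identical to the query"),
    ("pointsub", "MKWVLAHSGERC", "single substitution T->S"),
    ("gapped", "MKWVLAQQQQHTGERC", "four-residue insertion"),
    ("unrelated", "SGSGSGSG", "low-complexity, unrelated"),
    ("padded13", "MKWVLAHTGERCC", "length 13, exercises block padding"),
]

WORKED_EXAMPLE_SCORES = {
    "identical": 71,
    "pointsub": 67,
    "gapped": 56,
    "unrelated": 7,
    "padded13": 71,
}


def worked_example() -> Tuple[EncodedSequence, SequenceDatabase, dict]:
    """The frozen toy fixture: query, five-sequence db, expected score table.

    Expected scores (BLOSUM62, gap open 11, extend 1) are frozen constants;
    they were produced by the scalar oracle and are re-derivable with
    ``scripts/regen_worked_example.py``.
    """
    query = EncodedSequence.from_str(_WE_QUERY[0], _WE_QUERY[1], _WE_QUERY[2])
    db = SequenceDatabase(
        [EncodedSequence.from_str(i, s, d) for i, s, d in _WE_SUBJECTS]
    )
    return query, db, dict(WORKED_EXAMPLE_SCORES)


def worked_example_scoring() -> Tuple[ScoreMatrix, GapPenalties]:
    """The scoring system the worked example is frozen under."""
    return load_matrix("BLOSUM62"), make_gap_penalties(11, 1)
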