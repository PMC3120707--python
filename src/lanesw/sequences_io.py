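"""Protein sequence I/O: residue byte codes, FASTA, and a zero-separated binary form.

Residues are held as small integer codes so that the search engine can use
them directly as row/column indices into a code-indexed score table.  The
code assignment follows the classic protein-database byte layout: letters
A-I map to 1-9, K-N to 10-13, P-T to 14-18, V-Z to 19-23, then U, O and J
to 24, 26 and 27.  Code 0 is reserved as the inter-sequence separator and
block-padding symbol and never appears inside a sequence; code 25 is never
emitted.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, List, Union

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import EncodingError, FormatError, ParameterError

__all__ = [
    "NULL_CODE",
    "MAX_CODE",
    "EncodedSequence",
    "SequenceDatabase",
    "encode_residue",
    "decode_residues",
    "encode_sequence",
    "read_fasta",
    "write_fasta",
    "write_binary_db",
    "read_binary_db",
    "chunk_database",
]

NULL_CODE = 0
MAX_CODE = 27

# Encoding order: A-I, K-N, P-T, V-Z take codes 1-23, then U=24, O=26, J=27.
_CODE_LETTERS = "ABCDEFGHIKLMNPQRSTVWXYZ"
CODE_OF: dict[str, int] = {letter: i + 1 for i, letter in enumerate(_CODE_LETTERS)}
CODE_OF["U"] = 24
CODE_OF["O"] = 26
CODE_OF["J"] = 27

LETTER_OF: dict[int, str] = {code: letter for letter, code in CODE_OF.items()}

# Fast byte-level lookup: ASCII byte -> code, -1 when unsupported.
_ENCODE_LUT = np.full(256, -1, dtype=np.int16)
for _letter, _code in CODE_OF.items():
    _ENCODE_LUT[ord(_letter)] = _code
    _ENCODE_LUT[ord(_letter.lower())] = _code


def encode_residue(letter: str) -> int:
    """Return the integer code of one amino-acid letter (case-insensitive).

    Raises
    ------
    EncodingError
        If ``letter`` is not a single supported amino-acid/ambiguity letter.
    """
    if len(letter) != 1:
        raise EncodingError(f"expected a single character, got {letter!r}")
    code = _ENCODE_LUT[ord(letter)] if ord(letter) < 256 else -1
    if code < 0:
        raise EncodingError(f"unsupported residue character {letter!r}")
    return int(code)


def decode_residues(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` for valid (nonzero) codes."""
    return "".join(LETTER_OF[int(c)] for c in codes)


def encode_sequence(text: str, identifier: str = "?") -> np.ndarray:
    """Encode a residue string into a uint8 code array.

    ``identifier`` is only used to make error messages traceable.
    """
    raw = np.frombuffer(text.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise EncodingError(
            f"record {identifier!r}: unsupported residue character "
            f"{text[pos]!r} at position {pos + 1}"
        )
    return codes.astype(np.uint8)


@dataclass
class EncodedSequence:
    """A protein sequence as integer residue codes.

    Attributes
    ----------
    identifier : str
        First whitespace-delimited token of the FASTA header.
    residues : numpy.ndarray
        uint8 codes in 1..27 (never 0 or 25).
    description : str
        Remainder of the header line (may be empty).
    """

    identifier: str
    residues: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=np.uint8)
        if self.residues.size and (self.residues == NULL_CODE).any():
            raise FormatError(
                f"record {self.identifier!r}: residue code 0 is reserved"
            )

    @property
    def length(self) -> int:
        return int(self.residues.size)

    def __len__(self) -> int:
        return self.length

    @classmethod
    def from_str(
        cls, identifier: str, sequence: str, description: str = ""
    ) -> "EncodedSequence":
        return cls(identifier, encode_sequence(sequence, identifier), description)

    def to_str(self) -> str:
        return decode_residues(self.residues)


@dataclass
class SequenceDatabase:
    """An ordered protein sequence collection (file order is preserved)."""

    sequences: List[EncodedSequence] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.sequences)

    @property
    def total_residues(self) -> int:
        return sum(s.length for s in self.sequences)

    def __len__(self) -> int:
        return self.count

    def __iter__(self) -> Iterator[EncodedSequence]:
        return iter(self.sequences)

    def __getitem__(self, i: int) -> EncodedSequence:
        return self.sequences[i]


def _as_text_handle(source: Union[str, os.PathLike, IO[str]]) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    return open(os.fspath(source), "r"), True


def read_fasta(
    source: Union[str, os.PathLike, IO[str]],
    *,
    strip_stops: bool = False,
) -> Iterator[EncodedSequence]:
    """Yield :class:`EncodedSequence` records from FASTA in file order.

    Blank lines are ignored; wrapped sequence lines are joined.  ``'*'``
    characters are rejected unless ``strip_stops`` is set, in which case they
    are removed (score matrices used here have stop rows removed, so a stop
    symbol cannot be scored).

    Raises
    ------
    FormatError
        If sequence data precedes the first header line.
    EncodingError
        On an unencodable residue character, naming the record.
    """
    handle, owned = _as_text_handle(source)
    try:
        # SimpleFastaParser silently skips text before the first '>'; the
        # contract here is stricter.
        pre = []
        for line in handle:
            if not line.strip():
                continue
            if line.startswith(">"):
                pre.append(line)
                break
            raise FormatError("sequence data found before the first FASTA header")
        stream = io.StringIO("".join(pre) + handle.read())
        for header, seq in SimpleFastaParser(stream):
            parts = header.split(None, 1)
            identifier = parts[0] if parts else ""
            description = parts[1] if len(parts) > 1 else ""
            if "*" in seq:
                if strip_stops:
                    seq = seq.replace("*", "")
                else:
                    raise EncodingError(
                        f"record {identifier!r}: stop symbol '*' not allowed "
                        "(pass strip_stops=True to remove it)"
                    )
            yield EncodedSequence(identifier, encode_sequence(seq, identifier), description)
    finally:
        if owned:
            handle.close()


def read_fasta_db(
    source: Union[str, os.PathLike, IO[str]], *, strip_stops: bool = False
) -> SequenceDatabase:
    """Read a whole FASTA file into a :class:`SequenceDatabase`."""
    return SequenceDatabase(list(read_fasta(source, strip_stops=strip_stops)))


def write_fasta(
    db_or_seqs: Union[SequenceDatabase, Iterable[EncodedSequence]],
    sink: Union[str, os.PathLike, IO[str]],
    *,
    width: int = 60,
) -> None:
    """Write sequences as FASTA, wrapping residue lines at ``width``."""
    seqs = db_or_seqs.sequences if isinstance(db_or_seqs, SequenceDatabase) else list(db_or_seqs)
    if hasattr(sink, "write"):
        handle, owned = sink, False  # type: ignore[assignment]
    else:
        handle, owned = open(os.fspath(sink), "w"), True
    try:
        for seq in seqs:
            header = seq.identifier
            if seq.description:
                header += " " + seq.description
            handle.write(f">{header}\n")
            text = seq.to_str()
            for start in range(0, len(text), width):
                handle.write(text[start : start + width] + "\n")
    finally:
        if owned:
            handle.close()


# ---------------------------------------------------------------------------
# Simplified binary form: residue-code bytes with zero separators, plus a
# plain-text index sidecar (offset, length, header per line).

_INDEX_MAGIC = "#lanesw-index v1"


def write_binary_db(
    db: SequenceDatabase,
    seq_path: Union[str, os.PathLike],
    index_path: Union[str, os.PathLike],
) -> None:
    """Write ``db`` as a zero-separated code-byte file plus a text index.

    The sequence file is the concatenation of each sequence's residue-code
    bytes followed by one zero byte.  The index file has one tab-separated
    line per sequence: start offset, length, header text.
    """
    if db.count == 0:
        raise ParameterError("refusing to write an empty database")
    with open(os.fspath(seq_path), "wb") as sh, open(os.fspath(index_path), "w") as ih:
        ih.write(_INDEX_MAGIC + "\n")
        offset = 0
        for seq in db:
            sh.write(seq.residues.tobytes())
            sh.write(b"\x00")
            header = seq.identifier
            if seq.description:
                header += " " + seq.description
            ih.write(f"{offset}\t{seq.length}\t{header}\n")
            offset += seq.length + 1


def read_binary_db(
    seq_path: Union[str, os.PathLike],
    index_path: Union[str, os.PathLike],
) -> SequenceDatabase:
    """Read a database written by :func:`write_binary_db`.

    Raises
    ------
    FormatError
        On index/sequence mismatch, a missing zero separator, or an embedded
        zero byte inside a sequence.
    """
    data = np.fromfile(os.fspath(seq_path), dtype=np.uint8)
    seqs: List[EncodedSequence] = []
    expected_end = 0
    with open(os.fspath(index_path)) as ih:
        first = ih.readline().rstrip("\n")
        if first != _INDEX_MAGIC:
            raise FormatError(f"unrecognised index header {first!r}")
        for lineno, line in enumerate(ih, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                off_s, len_s, header = line.split("\t", 2)
                offset, length = int(off_s), int(len_s)
            except ValueError as exc:
                raise FormatError(f"index line {lineno}: malformed entry") from exc
            if offset + length + 1 > data.size:
                raise FormatError(
                    f"index line {lineno}: sequence file truncated "
                    f"(need {offset + length + 1} bytes, have {data.size})"
                )
            codes = data[offset : offset + length]
            if data[offset + length] != 0:
                raise FormatError(f"index line {lineno}: missing zero separator")
            if length and (codes == 0).any():
                raise FormatError(f"index line {lineno}: embedded zero byte")
            parts = header.split(None, 1)
            identifier = parts[0] if parts else ""
            description = parts[1] if len(parts) > 1 else ""
            seqs.append(EncodedSequence(identifier, codes.copy(), description))
            expected_end = offset + length + 1
    if expected_end != data.size:
        raise FormatError(
            f"sequence file has {data.size - expected_end} trailing bytes "
            "not covered by the index"
        )
    return SequenceDatabase(seqs)


def chunk_database(db: SequenceDatabase, n_chunks: int) -> List[SequenceDatabase]:
    """Partition ``db`` in order into ``n_chunks`` chunks.

    Chunk sequence counts differ by at most one; their concatenation equals
    the database.  Chunks beyond the sequence count are empty.
    """
    if n_chunks < 1:
        raise ParameterError(f"n_chunks must be >= 1, got {n_chunks}")
    base, extra = divmod(db.count, n_chunks)
    chunks: List[SequenceDatabase] = []
    start = 0
    for i in range(n_chunks):
        size = base + (1 if i < extra else 0)
        chunks.append(SequenceDatabase(db.sequences[start : start + size]))
        start += size
    return chunks
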