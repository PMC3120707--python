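import io

import pytest
from hypothesis import HealthCheck, settings

from lanesw.fixtures import FixtureSpec, generate_database
from lanesw.scoring import load_matrix, make_gap_penalties
from lanesw.sequences_io import read_fasta_db

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def gaps11_1():
    return make_gap_penalties(11, 1)


def make_db(seed, n, lo, hi, special_rate=0.0):
    """Small random database helper used across test modules."""
    spec = FixtureSpec(
        seed=seed,
        n_sequences=n,
        length_law=("uniform", lo, hi),
        special_symbol_rate=special_rate,
    )
    return read_fasta_db(io.StringIO(generate_database(spec)))


@pytest.fixture(scope="session")
def small_db():
    """60 sequences of lengths 1..90, including a few J/O/U/X residues."""
    return make_db(seed=11, n=60, lo=1, hi=90, special_rate=0.02)


@pytest.fixture(scope="session")
def small_query(small_db):
    from lanesw.fixtures import generate_query

    return generate_query(seed=12, length=48)
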