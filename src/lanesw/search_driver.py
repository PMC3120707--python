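"""Full database search: chunk scheduling, workers, hit list, reporting.

The database is partitioned into ``chunks_per_worker x workers`` chunks of
approximately equal sequence counts; chunks are handed to a pool of worker
threads as they become free.  Each chunk is processed shared-nothing by
:func:`lanesw.lane_engine.search_chunk`, and the merged results are
reassembled in chunk order, so the hit list and the per-sequence score table
are bit-identical for any worker count or chunk count.
"""

from __future__ import annotations

import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import List, Optional

from .errors import ParameterError
from .lane_engine import EngineConfig, search_chunk
from .scoring import GapPenalties, ScoreMatrix
from .sequences_io import EncodedSequence, SequenceDatabase, chunk_database

__all__ = [
    "SearchConfig",
    "Hit",
    "HitList",
    "SearchStats",
    "SearchResult",
    "run_search",
    "compute_gcups",
    "format_report",
]


@dataclass(frozen=True)
class SearchConfig:
    """Search-wide configuration (engine geometry nested in ``engine``)."""

    workers: int = 1
    chunks_per_worker: int = 100
    num_descriptions: int = 10
    engine: EngineConfig = field(default_factory=EngineConfig)

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ParameterError(f"workers must be >= 1, got {self.workers}")
        if self.chunks_per_worker < 1:
            raise ParameterError(
                f"chunks_per_worker must be >= 1, got {self.chunks_per_worker}"
            )
        if self.num_descriptions < 0:
            raise ParameterError("num_descriptions must be >= 0")


@dataclass(frozen=True)
class Hit:
    """One hit-list entry."""

    ordinal: int
    identifier: str
    description: str
    score: int
    tier: str


@dataclass
class HitList:
    """Top-K hits, score descending, ties broken by ascending ordinal."""

    hits: List[Hit]

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def __getitem__(self, i: int) -> Hit:
        return self.hits[i]


@dataclass
class SearchStats:
    """Problem size and throughput of one search."""

    query_length: int
    db_count: int
    db_residues: int
    cells: int
    seconds: float
    escalated: int

    @property
    def gcups(self) -> float:
        return compute_gcups(self.query_length, self.db_residues, self.seconds)


@dataclass
class SearchResult:
    hitlist: HitList
    scores: List[Hit]  # full per-sequence table in database order
    stats: SearchStats


def compute_gcups(query_length: int, total_residues: int, seconds: float) -> float:
    """Billion cell updates per second: m * N / t / 1e9."""
    if seconds <= 0:
        raise ParameterError(f"elapsed time must be > 0, got {seconds}")
    return query_length * total_residues / seconds / 1e9


def run_search(
    query: EncodedSequence,
    db: SequenceDatabase,
    matrix: ScoreMatrix,
    gaps: GapPenalties,
    config: SearchConfig = SearchConfig(),
) -> SearchResult:
    """Score every database sequence exactly once and rank the top hits.

    Results are invariant to ``workers`` and ``chunks_per_worker``.
    """
    if query.length == 0:
        raise ParameterError("query must be nonempty")
    if db.count == 0:
        raise ParameterError("database must be nonempty")
    n_chunks = min(config.workers * config.chunks_per_worker, db.count)
    chunks = chunk_database(db, n_chunks)
    start = time.perf_counter()

    def work(chunk: SequenceDatabase):
        return search_chunk(query, chunk.sequences, matrix, gaps, config.engine)

    if config.workers == 1:
        per_chunk = [work(c) for c in chunks]
    else:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            per_chunk = list(pool.map(work, chunks))
    elapsed = time.perf_counter() - start

    scores: List[Hit] = []
    ordinal = 0
    escalated = 0
    for chunk, results in zip(chunks, per_chunk):
        for seq, res in zip(chunk.sequences, results):
            scores.append(
                Hit(ordinal, seq.identifier, seq.description, res.score, res.tier)
            )
            if res.escalated:
                escalated += 1
            ordinal += 1
    ranked = sorted(scores, key=lambda h: (-h.score, h.ordinal))
    hitlist = HitList(ranked[: config.num_descriptions])
    stats = SearchStats(
        query_length=query.length,
        db_count=db.count,
        db_residues=db.total_residues,
        cells=query.length * db.total_residues,
        seconds=elapsed,
        escalated=escalated,
    )
    return SearchResult(hitlist, scores, stats)


def format_report(
    result: SearchResult,
    query: EncodedSequence,
    matrix: ScoreMatrix,
    gaps: GapPenalties,
    *,
    deterministic: bool = False,
) -> str:
    """Deterministic plain-text report of a completed search.

    With ``deterministic`` set, the timing/throughput line is suppressed so
    that identical searches produce byte-identical reports.
    """
    st = result.stats
    lines = [
        f"Query: {query.identifier} ({query.length} residues)",
        f"Database: {st.db_count} sequences, {st.db_residues} residues",
        f"Scoring: {matrix.name}, gap open {gaps.open}, gap extend {gaps.extend}",
        "",
        f"{'rank':>4}  {'score':>6}  {'tier':<5}  identifier",
    ]
    for rank, hit in enumerate(result.hitlist, start=1):
        lines.append(
            f"{rank:>4}  {hit.score:>6}  {hit.tier:<5}  {hit.identifier}"
        )
    lines.append("")
    lines.append(f"Cells: {st.cells}")
    lines.append(f"Sequences rescored in a wider tier: {st.escalated}")
    if not deterministic:
        lines.append(f"Elapsed: {st.seconds:.3f} s ({st.gcups:.3f} GCUPS)")
    return "\n".join(lines) + "\n"
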