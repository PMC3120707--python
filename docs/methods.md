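# Methods

## Model

`lanesw` computes exact optimal local alignment scores under the
Smith–Waterman model with Gotoh affine gap penalties.  For query `q`
(length m) and database sequence `d` (length n), with substitution matrix
`P` and a gap of length k costing `Q + (k-1)·R` (`Q = open + extend`,
`R = extend`), the recurrences are

    H[i][j] = max(0, H[i-1][j-1] + P[q_i, d_j], E[i][j], F[i][j])
    E[i][j] = max(H[i][j-1] - Q, E[i][j-1] - R)
    F[i][j] = max(H[i-1][j] - Q, F[i-1][j] - R)

with zero boundaries and `S = max H`.  The sweep is column-major over the
database sequence and keeps one H column, one E column and a running F
value — O(m) memory.  E and F are floored at zero in both the scalar and
lane implementations; this is score-preserving because H already takes a
maximum with zero, and it lets the biased stored form (below) represent E
and F in the same unsigned range as H.

Assumptions: protein sequences over the 26-letter amino-acid/ambiguity
alphabet; integer scores in `[-128, 127]`; scores only (no traceback, no
E-values — ranking is by raw optimal score).

## Residue encoding and scoring tables

Residues are byte codes: A–I → 1–9, K–N → 10–13, P–T → 14–18, V–Z → 19–23,
U → 24, O → 26, J → 27.  Code 0 is the sequence separator and padding
symbol; code 25 is never emitted.  Each `ScoreMatrix` exposes a 28×28
code-indexed table: code 0 (and the unassigned code 25) scores −128 against
everything, making padding provably inert — a padding column can only
lower H, so the running best never changes after a sequence's true end.
Letters absent from a matrix alphabet (U/O/J with the bundled matrices)
fall back to the ambiguity symbol 'X', or to the matrix minimum when no
fallback exists; this is a deliberate robustness choice so that modern
sequences containing selenocysteine/pyrrolysine or J ambiguity never crash
a search.  The eight bundled matrices are the standard NCBI BLOSUM/PAM
tables; their stop-codon ('*') rows and columns are removed at load time
because the encoding carries no stop symbol.

## Lane engine

The engine's parallel unit is a *lane*: L independent alignment problems
(default 16) advance in lock step, each lane holding one database sequence
at a time and refilling from the database stream in file order.  The
database axis is processed in blocks of B positions (default 4); within a
block, query rows are visited in groups of `query_unroll` (default 2), each
row covering the B block positions before the next row starts, i.e. eight
cells per lane per inner iteration at the defaults.  Sequences are padded
with 1..B−1 null symbols to a block boundary so that end-of-sequence
bookkeeping (emit score, reset lane state, load next sequence) runs once
per block, with a fast no-op path when nothing ended.  Block shape and lane
count are performance geometry only: any (L, B, unroll) produces
bit-identical scores, and the test suite asserts this across
L ∈ {1,4,8,16,32}, B ∈ {1,4}, unroll ∈ {1,2}.

A fresh score profile — substitution scores of every query-alphabet code
against the current B×L database residues — is built per block by direct
table indexing, replacing per-cell matrix lookups with contiguous reads.

### Biased saturated arithmetic and tier escalation

Narrow tiers store raw score `s` as `s + bias`, clamped to
`[bias, stored_max]`:

| tier | bias | stored range | raw capacity | lanes |
|------|------|--------------|--------------|-------|
| byte | 128  | 0..255       | 127 (7-bit)  | L     |
| word | 2^15 | 0..2^16−1    | 32767        | L/2   |
| exact| —    | unbounded    | —            | 1 (scalar) |

The lower clamp at the bias *is* the local-alignment zero floor, so the
core cell update is branch-free: saturated add of the diagonal carry and
the profile score, three maxima against E/F/S, two saturated subtractions
each for the next E and F.  The word tier mirrors the byte tier's
construction (the byte tier's geometry is the classic 16-lane SIMD layout;
the word bias is chosen symmetrically since only the byte bias is canonical).

Upper saturation can corrupt a score, so a lane is flagged when its running
best stored value reaches `stored_max − max(P)`.  This threshold is
conservative and provably sound: a saturating addition requires the
diagonal carry to exceed `stored_max − max(P)`, and the running best
dominates every H produced, so **every** potentially corrupted sequence is
flagged, while any sequence finishing below the threshold is exact.  The
cost is an occasional unnecessary rescore.  Flags are sticky per sequence
(the running best is monotone).  After a chunk finishes in the byte tier,
flagged sequences are rescored in the word tier, and any survivors with the
exact scalar recurrence (64-bit integers; effectively unbounded at protein
scale), so every reported score is exact.

The scalar recurrence and the per-block lane kernel are compiled with
numba (`nogil`, no on-disk cache); a pure-Python column sweep
(`gotoh_column_sweep`) and a numpy vector cell update
(`saturated_cell_update`) exist alongside for transparent column-level
testing of the compiled paths.

## Search driver

The database is split into `workers × chunks_per_worker` chunks (default
1 × 100) of near-equal sequence counts, processed shared-nothing by a
thread pool and merged in chunk order, so the hit list and per-sequence
score table are invariant to worker count and chunk count — a hard
contract, tested.  With pure-Python orchestration around the compiled
kernels, threads mainly bound memory (one chunk resident at a time) rather
than adding throughput; a single-worker mode is always available and is
the reference for exact reproducibility.  Hits are ranked by score
descending with ties broken by ascending database ordinal, which makes
output deterministic (tie order among equal scores is otherwise
unspecified in this problem).  Throughput is reported in GCUPS
(`m × N / t / 10⁹`).

## Synthetic data

The fixture generator emulates the *shape* of a protein knowledgebase, not
its biology: i.i.d. residues (uniform over the 20 standard amino acids by
default, with an optional BLOSUM-style background), a configurable length
law, and an optional per-position rate of the special residues J/O/U/X.
The default database spec — 2,000 sequences, discretised gamma lengths
(shape 2, scale 175, mean 350) — is a desk-scale stand-in chosen so that
lane refilling, chunk scheduling and padding are all exercised thousands of
times while a full verified sweep completes in seconds; the gamma law gives
the long right tail real databases show.  The default special-residue rate
is 0 (typical curated benchmark databases contain no J/O/U); tests enable
it explicitly to exercise the fallback mapping.  Because residues are
i.i.d., realistic homology structure is absent: random scores are small, so
tier escalation is driven by dedicated adversarial fixtures
(`generate_overflow_case` builds a homopolymer of the matrix's best
diagonal residue and verifies against the oracle that its self-score
exceeds the requested capacity).  Passing tests therefore demonstrate
*correctness* of scores on arbitrary sequence content, and say nothing
about biological sensitivity or score statistics.

## Verification strategy

Three independent layers anchor correctness:

1. the Gotoh recurrence is validated against exhaustive enumeration of all
   local alignments (all substring pairs × all monotone alignments with
   affine gap accounting) on short sequences, and cross-checked against a
   third-party affine-gap aligner (Biopython's `PairwiseAligner`);
2. the lane engine is compared cell-by-cell (stored H/E columns) and
   end-to-end (thousands of sequences, all bundled matrices, multiple gap
   settings) against the scalar recurrence, with exact equality required;
3. escalation paths are forced with adversarial fixtures and checked for
   exactness and correct tier provenance.

## Numerical and design choices

- Integer arithmetic everywhere; no floating point touches a score.
- Null score −128: the most negative representable value, so padding can
  never seed or extend an alignment in any tier.
- Overflow threshold `stored_max − max(P)`: chosen for provable soundness
  over minimal rescoring (the exact detection rule is otherwise a free
  parameter).
- F is reset along with H, E and S at lane boundaries; F never survives a
  block column anyway, but the reset makes the invariant explicit.
- Empty lanes (database exhausted) process null symbols and are excluded
  from emission; zero-length sequences score 0 and are emitted on load.
- Worst-case problem sizes in the shipped verification sweeps (2,000
  sequences of mean length 350 against a 375-residue query; 500
  enumeration pairs of length ≤ 6) were chosen as the smallest scales at
  which every engine mechanism (refill, padding, chunking, escalation) is
  exercised many times.

## Limitations

- Scores only: no traceback/alignment reconstruction and no statistical
  significance (E-values); ranking is by raw score.
- No hardware SIMD: lanes are an array axis compiled by numba, so absolute
  throughput is far below native vectorised implementations; the
  contribution here is the exact-by-construction engine semantics, not raw
  speed.
- Databases are processed in memory per chunk; multi-volume database
  formats and nucleotide searches are out of scope.
- Query profiles (PSSMs) are not supported; the profile builder assumes a
  plain query sequence.
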