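# lanesw

Lane-parallel Smith–Waterman protein database search with exact scores.

`lanesw` computes the optimal local alignment score of one protein query
against every sequence of a database using the Smith–Waterman algorithm with
Gotoh's affine-gap recurrences:

```
H[i][j] = max(0, H[i-1][j-1] + P[q_i, d_j], E[i][j], F[i][j])
E[i][j] = max(H[i][j-1] - Q, E[i][j-1] - R)      (gap in the query)
F[i][j] = max(H[i-1][j] - Q, F[i-1][j] - R)      (gap in the database)
S       = max over all i, j of H[i][j]
```

where `P` is a substitution score matrix (BLOSUM/PAM), `Q = open + extend`,
`R = extend`, and `S` is the reported score.  Unlike heuristic tools, every
score returned is exactly this optimum.

The engine exploits *inter-sequence* parallelism: residues from 16 database
sequences occupy 16 parallel lanes and are all compared against the same
query residue at once, which removes every data dependency between lanes.
Lanes are refilled from the database stream, in file order, as sequences
end.  For speed the dynamic-programming values are kept in biased saturated
7-bit form (raw score `s` stored as `s + 128`, clamped to `[128, 255]`, so
the lower clamp is the local-alignment zero floor), with blocks of 4
database positions and a query-unrolled inner loop covering 8 cells per
iteration.  Any sequence whose running best score approaches the 7-bit
ceiling is flagged and transparently rescored — first in a 15-bit tier at
half the lane count, then with exact unbounded integers — so saturation can
never silently corrupt a result.  This design is aimed at users who need
optimal-alignment sensitivity (curators, benchmark authors, method
developers) but want database-scan ergonomics: a FASTA (or simple binary)
database in, a ranked hit list out.

## Worked example

The package ships a frozen toy fixture: a 12-residue query `MKWVLAHTGERC`
and five subjects (identical; one substitution; a four-residue insertion;
an unrelated low-complexity sequence; and a 13-residue subject that
exercises block padding).  Searching it from the shell:

```sh
$ lanesw -i query.fasta -d toydb.fasta -v 5 --deterministic
Query: toyq (12 residues)
Database: 5 sequences, 61 residues
Scoring: BLOSUM62, gap open 11, gap extend 1

rank   score  tier   identifier
   1      71  byte   identical
   2      71  byte   padded13
   3      67  byte   pointsub
   4      56  byte   gapped
   5       7  byte   unrelated

Cells: 732
Sequences rescored in a wider tier: 0
```

The identical subject scores 71, the sum of BLOSUM62 diagonal entries of
the query (ties are broken by database order, so `padded13`, which contains
the full query, ranks second with the same score).  The single substitution
T→S costs `5 - 1 = 4` points (67); the four-residue insertion costs an
affine gap `Q + 3R = 12 + 3 = 15` (56); the unrelated subject's best local
match is a two-residue `TG`/`SG` alignment (7).  All five were computed in
the 7-bit byte tier; no rescoring was needed.  The same search is available
from Python:

```python
from lanesw import load_matrix, make_gap_penalties, run_search
from lanesw.fixtures import worked_example

query, db, expected = worked_example()
result = run_search(query, db, load_matrix("BLOSUM62"), make_gap_penalties(11, 1))
print([(h.identifier, h.score) for h in result.hitlist])
```

CLI options mirror classic database-search tools: `-i` query FASTA, `-d`
database (FASTA or a `<db>.seq`/`<db>.idx` binary pair), `-M` matrix name or
file, `-G`/`-E` gap open/extend, `-a` workers, `-v` hit-list size, plus
`--lanes`, `--block`, `--chunks`, `--deterministic` and
`--dump-scores <tsv>` for the full per-sequence score table.

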