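"""Brute-force local alignment oracle by exhaustive enumeration.

Independent of every dynamic-programming code path: the best local score is
found by enumerating all substring pairs and, for each pair, all monotone
global alignments of the two substrings, charging each gap run
Q + (len-1)*R.  Exponential, usable only for tiny sequences.
"""


def _best_global(q, d, pair_score, Q, R):
    """Max score over all global alignments of q and d (explicit enumeration)."""
    best = [None]

    def rec(i, j, acc, state):
        # state: 0 = last move was a match (or start), 1 = gap in the
        # database (query consumed), 2 = gap in the query (database consumed)
        if i == len(q) and j == len(d):
            if best[0] is None or acc > best[0]:
                best[0] = acc
            return
        if i < len(q) and j < len(d):
            rec(i + 1, j + 1, acc + pair_score(q[i], d[j]), 0)
        if i < len(q):
            rec(i + 1, j, acc - (R if state == 1 else Q), 1)
        if j < len(d):
            rec(i, j + 1, acc - (R if state == 2 else Q), 2)

    rec(0, 0, 0, 0)
    return best[0]


def brute_local_score(q, d, pair_score, Q, R):
    """Best local alignment score of sequences ``q`` and ``d``.

    ``q`` and ``d`` are any indexable residue sequences and ``pair_score`` a
    two-argument substitution score function.  The empty alignment (score 0)
    is always admissible.
    """
    best = 0
    for a in range(len(q) + 1):
        for b in range(a, len(q) + 1):
            for c in range(len(d) + 1):
                for e in range(c, len(d) + 1):
                    if b == a and e == c:
                        continue
                    s = _best_global(q[a:b], d[c:e], pair_score, Q, R)
                    if s is not None and s > best:
                        best = s
    return best
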