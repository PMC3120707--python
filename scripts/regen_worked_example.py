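#!/usr/bin/env python
"""Recompute the frozen worked-example score table with the scalar oracle.

Prints the expected-score dictionary that is frozen in
``lanesw.fixtures.WORKED_EXAMPLE_SCORES`` and exits nonzero if the frozen
values have drifted from a fresh oracle computation.
"""

import sys

from lanesw.fixtures import worked_example, worked_example_scoring
from lanesw.reference_align import gotoh_local_score


def main() -> int:
    query, db, frozen = worked_example()
    matrix, gaps = worked_example_scoring()
    fresh = {
        s.identifier: gotoh_local_score(query, s, matrix, gaps) for s in db
    }
    print("WORKED_EXAMPLE_SCORES = {")
    for key, value in fresh.items():
        print(f'    "{key}": {value},')
    print("}")
    if fresh != frozen:
        print("frozen table is STALE:", frozen, file=sys.stderr)
        return 1
    print("frozen table matches the oracle.")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
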