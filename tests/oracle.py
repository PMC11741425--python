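"""Independent regex-based run-length oracle for repeat counting.

Maximal runs of complete motif copies are located with the regular
expression engine (one greedy pattern per equivalence-class member), then
deduplicated per genomic interval keeping the longest run (ties: leftmost
start, lexicographic member).  Deliberately shares no code with the
frame-scanning implementation in the package.
"""

import re
from typing import Dict, Tuple


def brute_force_counts(sequence: str, members,
                       ) -> Tuple[Dict[int, int], Dict[int, int]]:
    seq = sequence.upper()
    n = len(next(iter(members)))
    candidates = []
    for member in sorted(members):
        # lookahead enumerates every run start (plain finditer would skip a
        # maximal run starting inside an earlier overlapping match)
        pattern = re.compile(f"(?=((?:{member})+))")
        for match in pattern.finditer(seq):
            start = match.start()
            if start >= n and seq[start - n:start] == member:
                continue                     # not left-maximal
            k = len(match.group(1)) // n
            candidates.append((-(k), start, start + k * n, member))
    candidates.sort()
    occupied = [False] * len(seq)
    counts_a: Dict[int, int] = {}
    for negk, start, end, _ in candidates:
        if any(occupied[start:end]):
            continue
        for i in range(start, end):
            occupied[i] = True
        counts_a[-negk] = counts_a.get(-negk, 0) + 1

    counts_b: Dict[int, int] = {}
    run = 0
    for i, base in enumerate(seq):
        if not occupied[i] and base != "N":
            run += 1
        else:
            if run:
                counts_b[run] = counts_b.get(run, 0) + 1
            run = 0
    if run:
        counts_b[run] = counts_b.get(run, 0) + 1
    return counts_a, counts_b
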