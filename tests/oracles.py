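"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's vectorised/greedy code paths: the
matcher oracle is a per-offset character scan, the interval oracle
enumerates every subset.
"""

from __future__ import annotations

import itertools

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def hamming_nothing_matches_n(a: str, b: str) -> int:
    """Hamming distance where N never matches anything (including N)."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def brute_force_scan(
    spacer_seq: str, contig_seq: str, max_mismatches: int
) -> list[tuple[int, str, int]]:
    """Every full-length placement on either strand within the threshold.

    Returns (1-based contig start, strand, distance), sorted by
    (start, strand).
    """
    L = len(spacer_seq)
    hits = []
    rc = revcomp(spacer_seq)
    for offset in range(len(contig_seq) - L + 1):
        window = contig_seq[offset : offset + L]
        for strand, pattern in (("+", spacer_seq), ("-", rc)):
            d = hamming_nothing_matches_n(pattern, window)
            if d <= max_mismatches:
                hits.append((offset + 1, strand, d))
    hits.sort()
    return hits


def max_nonoverlapping_exhaustive(intervals: list[tuple[int, int]]) -> int:
    """Maximum pairwise non-overlapping subset by subset enumeration.

    Closed-interval overlap: [a,b] and [c,d] overlap iff a <= d and c <= b.
    Exponential; only for instances of ~12 intervals or fewer.
    """
    best = 0
    for r in range(len(intervals), 0, -1):
        if r <= best:
            break
        for subset in itertools.combinations(intervals, r):
            ok = all(
                not (a <= d and c <= b)
                for (a, b), (c, d) in itertools.combinations(subset, 2)
            )
            if ok:
                best = max(best, r)
                break
    return best
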