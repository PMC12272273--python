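"""Independent brute-force oracles for the search and run statistics.

Deliberately naive: per-position string comparison at every offset and
strand, and exhaustive O(k^2) window enumeration. These share no code with
the vectorized implementations they check.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_scan(fragment: str, transcript: str, min_identities: int
               ) -> list[tuple[int, str, int, tuple[int, ...]]]:
    """Every full-length gapless placement on both strands, by double loop.

    Returns tuples ``(t_start 1-based, strand, identities, guide mismatch
    positions)`` for placements with at least ``min_identities`` matches.
    N never counts as an identity.
    """
    k = len(fragment)
    results = []
    for strand, query in (("forward", fragment),
                          ("reverse", naive_revcomp(fragment))):
        for offset in range(len(transcript) - k + 1):
            window = transcript[offset:offset + k]
            mismatches = []
            for j in range(k):
                a, b = query[j], window[j]
                if a != b or a == "N" or b == "N":
                    # map placed-strand index back to guide coordinates
                    guide = j + 1 if strand == "forward" else k - j
                    mismatches.append(guide)
            identities = k - len(mismatches)
            if identities >= min_identities:
                results.append((offset + 1, strand, identities,
                                tuple(sorted(mismatches))))
    return results


def naive_run_statistics(positions, k: int, m: int) -> tuple[int, int]:
    """Longest perfect run and best near-perfect stretch by full enumeration."""
    mm = set(positions)
    longest_perfect = 0
    best_near = 0
    for a in range(1, k + 1):
        for b in range(a, k + 1):
            n_mm = sum(1 for p in mm if a <= p <= b)
            if n_mm == 0:
                longest_perfect = max(longest_perfect, b - a + 1)
            if n_mm <= m:
                best_near = max(best_near, b - a + 1)
    return longest_perfect, best_near
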