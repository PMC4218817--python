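"""Independent brute-force oracles used to cross-check the scanner.

These deliberately avoid the package's run/groupby machinery: they use
naive window scans so that agreement with the implementation is a real
two-route check.
"""

from __future__ import annotations


def greedy_disjoint(sequence: str, trigram: str) -> int:
    """Left-to-right greedy count of disjoint occurrences of a trigram."""
    count = 0
    i = 0
    while i + 3 <= len(sequence):
        if sequence[i : i + 3] == trigram:
            count += 1
            i += 3
        else:
            i += 1
    return count


def all_match_positions(sequence: str, trigram: str) -> list[int]:
    """Every window position where the trigram matches (overlaps allowed)."""
    return [
        i for i in range(len(sequence) - 2) if sequence[i : i + 3] == trigram
    ]


def brute_runs(sequence: str, residue: str, min_length: int = 3) -> list[tuple[int, int]]:
    """(start, length) of maximal runs found by checking every window."""
    out = []
    n = len(sequence)
    for start in range(n):
        if sequence[start] != residue:
            continue
        if start > 0 and sequence[start - 1] == residue:
            continue  # not a run start
        end = start
        while end < n and sequence[end] == residue:
            end += 1
        if end - start >= min_length:
            out.append((start, end - start))
    return out


def brute_units(sequence: str, residue: str) -> int:
    return sum(length // 3 for _, length in brute_runs(sequence, residue))


def quartiles_by_sorting(values: list[float], q: float) -> float:
    """Linear interpolation between closest order statistics, from scratch."""
    data = sorted(values)
    h = (len(data) - 1) * q
    lo = int(h)
    hi = min(lo + 1, len(data) - 1)
    frac = h - lo
    return data[lo] + (data[hi] - data[lo]) * frac
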