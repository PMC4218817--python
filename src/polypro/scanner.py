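"""Homopolymer run detection, repeat-unit assignment and PPG counting.

The census is built from three primitives:

* a *maximal run* of a residue: ``n`` consecutive identical residues whose
  flanking positions (or the sequence ends) hold a different residue —
  the ``XPnX`` pattern with sequence boundaries treated as non-matching
  flanks, so a protein beginning or ending in prolines still counts;
* the *unit rule*: a run of length ``n`` contributes ``n // 3`` repeat
  units, i.e. runs of 3–5 residues count as one unit, 6–8 as two, and so
  on — the greedy number of disjoint triplets that fit inside the run;
* the *PPG count*: occurrences of the exact tripeptide Pro-Pro-Gly.  PPG
  cannot overlap itself (its first and last residues differ), so the
  non-overlapping count equals the number of match positions.

PPP (polyproline) units and PPG occurrences are counted by independent
scans of the same sequence: a substring ``PPPPG`` contributes one PPP unit
and one PPG.  Ambiguity letters (X, B, Z, U, O) never extend a run — they
count toward protein length but break any repeat they interrupt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Mapping, Sequence

from polypro.io import ProteinRecord

__all__ = [
    "STANDARD_AA",
    "RepeatRun",
    "ProteinMotifProfile",
    "find_runs",
    "run_units",
    "count_ppg",
    "triplet_units",
    "scan_protein",
]

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_AA = tuple("ACDEFGHIKLMNPQRSTVWY")

_STANDARD_SET = frozenset(STANDARD_AA)


@dataclass(frozen=True)
class RepeatRun:
    """One maximal homopolymer run.

    ``start`` is a 0-based index into the protein sequence; ``length`` the
    number of consecutive identical residues; ``units`` the repeat units
    the run contributes under the division-by-3 rule.
    """

    residue: str
    start: int
    length: int

    @property
    def units(self) -> int:
        return self.length // 3

    @property
    def end(self) -> int:
        """Exclusive end index."""
        return self.start + self.length


def run_units(length: int) -> int:
    """Repeat units of a run: the whole number after dividing length by 3.

    Runs of 3, 4 or 5 residues count as one unit; 6, 7 or 8 as two units;
    lengths below 3 contribute nothing.  Equivalently, the number of
    disjoint triplets that fit in the run.  There is no upper cap.
    """
    if length < 0:
        raise ValueError(f"run length must be non-negative, got {length}")
    return length // 3


def _check_residue(residue: str) -> None:
    if len(residue) != 1 or not residue.isalpha() or not residue.isupper():
        raise ValueError(f"residue must be a single uppercase letter, got {residue!r}")


def find_runs(sequence: str, residue: str, min_length: int = 3) -> list[RepeatRun]:
    """All maximal runs of ``residue`` with length ≥ ``min_length``.

    Runs are returned in ascending start order; maximality means the
    characters immediately before and after the run (when inside the
    sequence) differ from ``residue``, with sequence boundaries behaving
    as non-matching flanks.
    """
    _check_residue(residue)
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    runs: list[RepeatRun] = []
    pos = 0
    for char, group in groupby(sequence):
        length = sum(1 for _ in group)
        if char == residue and length >= min_length:
            runs.append(RepeatRun(residue=residue, start=pos, length=length))
        pos += length
    return runs


def count_ppg(sequence: str) -> int:
    """Non-overlapping occurrences of the exact trigram Pro-Pro-Gly.

    Because PPG cannot overlap itself, a left-to-right non-overlapping scan
    finds every match position; ``str.count`` implements exactly that.
    """
    return sequence.count("PPG")


def triplet_units(sequence: str, residue: str) -> int:
    """Total triplet units of ``residue``: Σ ⌊n/3⌋ over its maximal runs."""
    _check_residue(residue)
    return sum(run.units for run in find_runs(sequence, residue, min_length=3))


@dataclass(frozen=True)
class ProteinMotifProfile:
    """Per-protein motif and repeat census.

    ``runs`` lists the maximal proline runs of length ≥ 3; ``triplet_units``
    maps each of the 20 standard residues to its total triplet units, so
    ``triplet_units['P'] == ppp_units`` always.  ``residue_counts`` holds
    per-letter occurrence counts (including ambiguity letters), summing to
    ``length``.
    """

    protein_id: str
    gene_id: str
    description: str
    length: int
    ppp_units: int
    ppg_count: int
    proline_count: int
    runs: tuple[RepeatRun, ...]
    triplet_units: Mapping[str, int]
    residue_counts: Mapping[str, int]


def scan_protein(record: ProteinRecord) -> ProteinMotifProfile:
    """Build the full motif profile of one protein in a single pass.

    Maximal runs of every residue are enumerated once; proline runs of
    length ≥ 3 are kept, triplet units accumulated for all 20 standard
    letters, and PPG counted by an independent scan of the sequence.
    """
    seq = record.sequence
    units: dict[str, int] = dict.fromkeys(STANDARD_AA, 0)
    counts: dict[str, int] = {}
    p_runs: list[RepeatRun] = []
    pos = 0
    for char, group in groupby(seq):
        length = sum(1 for _ in group)
        counts[char] = counts.get(char, 0) + length
        if char in _STANDARD_SET and length >= 3:
            units[char] += length // 3
            if char == "P":
                p_runs.append(RepeatRun(residue="P", start=pos, length=length))
        pos += length
    return ProteinMotifProfile(
        protein_id=record.protein_id,
        gene_id=record.gene_id,
        description=record.description,
        length=len(seq),
        ppp_units=units["P"],
        ppg_count=count_ppg(seq),
        proline_count=counts.get("P", 0),
        runs=tuple(p_runs),
        triplet_units=units,
        residue_counts=counts,
    )


def scan_proteome(records: Sequence[ProteinRecord]) -> list[ProteinMotifProfile]:
    """Profile every protein of a proteome independently."""
    return [scan_protein(record) for record in records]
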