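"""Proteome-level aggregation: unit totals, calibrated frequencies,
run-length histograms, unit-threshold gene groups, length and composition
statistics.

Frequencies are calibrated against proteome size: motif units per 10,000
amino acids (``total units / total residues × 10⁴``) and proline usage as a
percentage of all residues.  Integer totals are exact sums over per-protein
profiles; frequencies are carried at full precision internally and rounded
half-up only when tables are serialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from polypro.scanner import STANDARD_AA, ProteinMotifProfile

__all__ = [
    "ProteomeSummary",
    "RunLengthTable",
    "GeneGroup",
    "LengthStats",
    "AAComposition",
    "round_half_up",
    "summarize_proteome",
    "run_length_table",
    "units_from_table",
    "gene_groups",
    "length_stats",
    "aa_composition",
]

#: Explicit histogram buckets for run lengths; longer runs go to ">10".
RUN_BUCKETS = tuple(range(3, 11))


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Matches the rounding convention of the reported tables (e.g. a raw
    frequency of 8.275 prints as 8.28); Python's builtin ``round`` uses
    banker's rounding and would disagree on exact ties.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProteomeSummary:
    """Proteome-level totals and calibrated frequencies (one table row).

    Frequencies are derived properties of the stored integer totals, so
    recomputing them always reproduces the stored values exactly.
    """

    species_label: str
    n_orfs: int
    total_aa: int
    total_ppp_units: int
    total_ppg: int
    total_proline: int

    def __post_init__(self) -> None:
        if self.n_orfs <= 0:
            raise ValueError("proteome summary requires at least one protein")
        if self.total_aa <= 0:
            raise ValueError("proteome summary requires a positive residue total")

    @property
    def ppp_freq_per_1e4(self) -> float:
        return self.total_ppp_units / self.total_aa * 1e4

    @property
    def ppg_freq_per_1e4(self) -> float:
        return self.total_ppg / self.total_aa * 1e4

    @property
    def proline_pct(self) -> float:
        return self.total_proline / self.total_aa * 100.0


def summarize_proteome(
    profiles: Sequence[ProteinMotifProfile], label: str
) -> ProteomeSummary:
    """Sum per-protein profiles into a proteome summary row."""
    if not profiles:
        raise ValueError("cannot summarize an empty proteome")
    return ProteomeSummary(
        species_label=label,
        n_orfs=len(profiles),
        total_aa=sum(p.length for p in profiles),
        total_ppp_units=sum(p.ppp_units for p in profiles),
        total_ppg=sum(p.ppg_count for p in profiles),
        total_proline=sum(p.proline_count for p in profiles),
    )


@dataclass(frozen=True)
class RunLengthTable:
    """Histogram of maximal proline-run lengths (3..10 plus a ">10" bucket).

    ``overflow_lengths`` preserves the exact lengths behind the ">10"
    bucket when they are known (they are needed to recompute unit totals);
    ``None`` means only the bucket count is known, as when a printed table
    row is taken as input.
    """

    counts: Mapping[int, int]
    overflow_count: int = 0
    overflow_lengths: tuple[int, ...] | None = ()

    def __post_init__(self) -> None:
        counts = {n: int(self.counts.get(n, 0)) for n in RUN_BUCKETS}
        if any(c < 0 for c in counts.values()) or self.overflow_count < 0:
            raise ValueError("run-length counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        if self.overflow_lengths is not None:
            lengths = tuple(sorted(self.overflow_lengths))
            if any(m <= RUN_BUCKETS[-1] for m in lengths):
                raise ValueError("overflow lengths must exceed the last bucket (10)")
            if len(lengths) != self.overflow_count:
                raise ValueError(
                    f"overflow bucket holds {self.overflow_count} runs but "
                    f"{len(lengths)} overflow lengths were supplied"
                )
            object.__setattr__(self, "overflow_lengths", lengths)

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[int, int],
        overflow_count: int = 0,
        overflow_lengths: tuple[int, ...] | None = None,
    ) -> "RunLengthTable":
        """Build a table from per-length counts, e.g. a printed table row."""
        if overflow_lengths is None and overflow_count:
            return cls(counts=counts, overflow_count=overflow_count, overflow_lengths=None)
        return cls(
            counts=counts,
            overflow_count=overflow_count,
            overflow_lengths=overflow_lengths or (),
        )

    @property
    def total_runs(self) -> int:
        return sum(self.counts.values()) + self.overflow_count

    @property
    def pct_3p_defined(self) -> bool:
        return self.total_runs > 0

    @property
    def pct_3p(self) -> float:
        """Triple-proline runs as a percentage of all runs; 0 when empty."""
        total = self.total_runs
        if total == 0:
            return 0.0
        return self.counts[3] / total * 100.0


def run_length_table(profiles: Iterable[ProteinMotifProfile]) -> RunLengthTable:
    """Histogram all maximal proline runs (length ≥ 3) of a proteome."""
    counts = dict.fromkeys(RUN_BUCKETS, 0)
    overflow: list[int] = []
    for profile in profiles:
        for run in profile.runs:
            if run.length <= RUN_BUCKETS[-1]:
                counts[run.length] += 1
            else:
                overflow.append(run.length)
    return RunLengthTable(
        counts=counts, overflow_count=len(overflow), overflow_lengths=tuple(overflow)
    )


def units_from_table(
    table: RunLengthTable, overflow_lengths: Sequence[int] | None = None
) -> int:
    """Total repeat units implied by a run-length histogram.

    Σ count(n) × ⌊n/3⌋ over the explicit buckets, plus Σ ⌊m/3⌋ over the
    exact lengths of the ">10" runs.  The overflow lengths must be supplied
    (either here or stored on the table) whenever the ">10" bucket is
    non-empty, because the bucket count alone under-determines the units.
    """
    if overflow_lengths is None:
        overflow_lengths = table.overflow_lengths
    if overflow_lengths is None:
        overflow_lengths = ()
    if len(overflow_lengths) != table.overflow_count:
        raise ValueError(
            f"need exactly {table.overflow_count} overflow lengths, "
            f"got {len(overflow_lengths)}"
        )
    units = sum(count * (n // 3) for n, count in table.counts.items())
    units += sum(m // 3 for m in overflow_lengths)
    return units


@dataclass(frozen=True)
class GeneGroup:
    """Genes whose unit count for a motif reaches a threshold."""

    motif: str
    threshold: int
    member_gene_ids: frozenset[str]
    n_proteome: int

    @property
    def count(self) -> int:
        return len(self.member_gene_ids)

    @property
    def pct_of_proteome(self) -> float:
        return self.count / self.n_proteome * 100.0


def _motif_units(profile: ProteinMotifProfile, motif: str) -> int:
    if motif == "PPP":
        return profile.ppp_units
    if motif == "PPG":
        return profile.ppg_count
    if len(motif) == 3 and len(set(motif)) == 1:
        return profile.triplet_units.get(motif[0], 0)
    raise ValueError(f"unsupported motif {motif!r}: expected PPP, PPG or a triplet XXX")


def gene_groups(
    profiles: Sequence[ProteinMotifProfile],
    motif: str,
    thresholds: Sequence[int] = (1, 2, 3),
) -> list[GeneGroup]:
    """Gene groups at each unit threshold (≥1, ≥2, ≥3 ... units).

    Groups nest: every member at threshold k+1 is a member at k.
    """
    thresholds = list(thresholds)
    if len(set(thresholds)) != len(thresholds) or any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be distinct positive integers")
    n = len(profiles)
    groups = []
    for threshold in sorted(thresholds):
        members = frozenset(
            p.gene_id for p in profiles if _motif_units(p, motif) >= threshold
        )
        groups.append(
            GeneGroup(motif=motif, threshold=threshold, member_gene_ids=members, n_proteome=n)
        )
    return groups


@dataclass(frozen=True)
class LengthStats:
    """Five-number summary plus mean of protein lengths (box-plot statistics).

    Quartiles use linear interpolation between closest order statistics.
    """

    n: int
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float


def length_stats(
    profiles: Sequence[ProteinMotifProfile] | Sequence[int],
) -> LengthStats:
    """Box-and-whisker statistics of protein lengths.

    Accepts profiles or raw integer lengths.  Quartiles are computed by
    linear interpolation between closest order statistics (numpy's default
    percentile method); the interpolation method is part of the reported
    metadata since box-plot conventions differ between tools.
    """
    lengths = [
        p.length if isinstance(p, ProteinMotifProfile) else int(p) for p in profiles
    ]
    if not lengths:
        raise ValueError("length statistics require at least one protein")
    arr = np.asarray(lengths, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return LengthStats(
        n=len(lengths),
        min=float(arr.min()),
        q1=float(q1),
        median=float(med),
        mean=float(arr.mean()),
        q3=float(q3),
        max=float(arr.max()),
    )


@dataclass(frozen=True)
class AAComposition:
    """Per-residue occurrence and triplet-unit totals for one proteome.

    ``counts``/``frequencies`` cover the 20 standard residues plus an
    ``"other"`` key pooling ambiguity letters, so counts sum to the total
    residue count.  Triplet-unit frequencies are units per residue.
    """

    total_aa: int
    counts: Mapping[str, int]
    frequencies: Mapping[str, float]
    triplet_unit_totals: Mapping[str, int]
    triplet_unit_frequencies: Mapping[str, float]


def aa_composition(profiles: Sequence[ProteinMotifProfile]) -> AAComposition:
    """Aggregate 20-residue occurrence counts and triplet units."""
    if not profiles:
        raise ValueError("composition requires at least one protein")
    counts = dict.fromkeys(STANDARD_AA, 0)
    other = 0
    units = dict.fromkeys(STANDARD_AA, 0)
    total_aa = 0
    for profile in profiles:
        total_aa += profile.length
        for residue, c in profile.residue_counts.items():
            if residue in counts:
                counts[residue] += c
            else:
                other += c
        for residue, u in profile.triplet_units.items():
            units[residue] += u
    counts["other"] = other
    freqs = {residue: c / total_aa for residue, c in counts.items()}
    unit_freqs = {residue: u / total_aa for residue, u in units.items()}
    return AAComposition(
        total_aa=total_aa,
        counts=counts,
        frequencies=freqs,
        triplet_unit_totals=units,
        triplet_unit_frequencies=unit_freqs,
    )
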