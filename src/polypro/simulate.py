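"""Synthetic proteomes with planted repeats, and synthetic ortholog tables.

Every pipeline stage needs ground truth without downloading a database.
:func:`generate_proteome` draws background residues i.i.d. from a
configurable composition and plants homopolymer runs (and PPG trigrams) of
exact, known lengths at random non-overlapping positions.  Flanking
positions of each plant are redrawn to exclude the planted residue (and,
to the right of a proline run, glycine), so every planted run is maximal
at exactly its planted length and no accidental PPG forms at a plant
boundary.  With the background probability of the planted residue set to
zero the scanner must therefore recover the plants exactly; with a
realistic background the observed totals fluctuate around a closed-form
expectation computed by :func:`expected_frequencies`.

:func:`generate_ortholog_tables` emits pairwise InParanoid-style tables
whose score-1.0 structure encodes designed, nested pool memberships, so
pool construction can be checked by exact round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from polypro.io import ProteinRecord
from polypro.orthologs import OrthologRecord
from polypro.scanner import STANDARD_AA

__all__ = [
    "SyntheticProteomeSpec",
    "GroundTruth",
    "PlantedRun",
    "SyntheticOrthologSet",
    "generate_proteome",
    "generate_ortholog_tables",
    "expected_frequencies",
    "ExpectedTotals",
    "uniform_composition",
]

_PLACEMENT_RETRIES = 1000


def uniform_composition() -> dict[str, float]:
    """Uniform background over the 20 standard residues (each 0.05).

    This puts proline at 5% of residues, inside the 4.3–6.3% range
    observed across real proteomes from bacteria to human.
    """
    return {aa: 1.0 / len(STANDARD_AA) for aa in STANDARD_AA}


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Recipe for a synthetic proteome.

    ``length`` is either a fixed integer, ``("uniform", lo, hi)`` (inclusive
    integer range), or ``("lognormal", mu, sigma)`` on the log scale.
    ``planted_runs`` lists ``(residue, run_length, count)`` triples: ``count``
    runs of exactly ``run_length`` copies of ``residue``, distributed over
    randomly chosen proteins.  ``ppg_plants`` PPG trigrams are planted the
    same way.  Generation is deterministic under a fixed ``seed``.
    """

    n_proteins: int
    length: int | tuple = 300
    composition: Mapping[str, float] | None = None
    planted_runs: tuple[tuple[str, int, int], ...] = ()
    ppg_plants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        comp = dict(self.composition) if self.composition is not None else uniform_composition()
        unknown = set(comp) - set(STANDARD_AA)
        if unknown:
            raise ValueError(f"composition contains non-standard residues: {sorted(unknown)}")
        for aa in STANDARD_AA:
            comp.setdefault(aa, 0.0)
        if any(p < 0 for p in comp.values()):
            raise ValueError("composition probabilities must be non-negative")
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition probabilities sum to {total}, expected 1")
        object.__setattr__(self, "composition", comp)
        plants = tuple((str(r), int(n), int(c)) for r, n, c in self.planted_runs)
        for residue, n, count in plants:
            if residue not in STANDARD_AA:
                raise ValueError(f"cannot plant runs of non-standard residue {residue!r}")
            if n < 3:
                raise ValueError(f"planted run length must be >= 3, got {n}")
            if count < 0:
                raise ValueError("planted run count must be non-negative")
        object.__setattr__(self, "planted_runs", plants)
        if self.ppg_plants < 0:
            raise ValueError("ppg_plants must be non-negative")


@dataclass(frozen=True)
class PlantedRun:
    """One planted homopolymer run in one protein (ground truth)."""

    protein_index: int
    residue: str
    start: int
    length: int

    @property
    def units(self) -> int:
        return self.length // 3


@dataclass(frozen=True)
class GroundTruth:
    """Exact planted structure of a synthetic proteome.

    ``free_positions`` counts, per protein, the background positions not
    claimed by a plant or a forced flank — the positions where background
    repeats can still arise.  Planted totals are recomputable from the
    per-protein lists; background contributions come on top of them (and
    vanish when the background probability of the planted residue is 0).
    """

    protein_lengths: tuple[int, ...]
    planted_runs: tuple[PlantedRun, ...]
    ppg_positions: tuple[tuple[int, int], ...]  # (protein_index, start)
    free_positions: tuple[int, ...]

    @property
    def planted_units(self) -> int:
        return sum(run.units for run in self.planted_runs)

    @property
    def planted_ppg(self) -> int:
        return len(self.ppg_positions)

    @property
    def planted_prolines(self) -> int:
        return sum(r.length for r in self.planted_runs if r.residue == "P") + 2 * len(
            self.ppg_positions
        )

    def runs_for_protein(self, index: int) -> list[PlantedRun]:
        return sorted(
            (r for r in self.planted_runs if r.protein_index == index),
            key=lambda r: r.start,
        )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _sample_length(rng: np.random.Generator, length: int | tuple) -> int:
    if isinstance(length, int):
        return length
    kind = length[0]
    if kind == "uniform":
        _, lo, hi = length
        return int(rng.integers(int(lo), int(hi) + 1))
    if kind == "lognormal":
        _, mu, sigma = length
        return max(3, int(round(rng.lognormal(float(mu), float(sigma)))))
    raise ValueError(f"unknown length sampler {length!r}")


def _draw_excluding(
    rng: np.random.Generator,
    letters: list[str],
    probs: np.ndarray,
    excluded: set[str],
) -> str:
    keep = [i for i, aa in enumerate(letters) if aa not in excluded]
    weights = probs[keep]
    total = weights.sum()
    if total <= 0:  # degenerate composition: fall back to uniform over allowed
        weights = np.ones(len(keep))
        total = float(len(keep))
    weights = weights / total
    return letters[keep[int(rng.choice(len(keep), p=weights))]]


def generate_proteome(
    spec: SyntheticProteomeSpec,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate a synthetic proteome with exactly known planted structure.

    Plants are assigned to proteins by a dedicated random stream, then each
    protein is generated from its own ``(seed, protein index)`` stream, so
    any record is reproducible independently of generation order.  Plant
    placement uses rejection sampling (with a retry cap) against an
    occupancy mask that includes one flank position on each side, so plants
    can neither overlap nor merge; an infeasible spec is a hard error.
    """
    letters = list(STANDARD_AA)
    probs = np.array([spec.composition[aa] for aa in letters])

    # Assign each plant instance to a protein with a stream separate from
    # the per-protein streams.
    assign_rng = _rng(spec.seed, 0)
    plant_instances: list[tuple[str, int]] = []  # (kind/residue, run length)
    for residue, n, count in spec.planted_runs:
        plant_instances.extend([(residue, n)] * count)
    ppg_instances = spec.ppg_plants
    owners = assign_rng.integers(0, spec.n_proteins, size=len(plant_instances))
    ppg_owners = assign_rng.integers(0, spec.n_proteins, size=ppg_instances)

    per_protein_runs: dict[int, list[tuple[str, int]]] = {}
    for owner, inst in zip(owners, plant_instances):
        per_protein_runs.setdefault(int(owner), []).append(inst)
    per_protein_ppg: dict[int, int] = {}
    for owner in ppg_owners:
        per_protein_ppg[int(owner)] = per_protein_ppg.get(int(owner), 0) + 1

    records: list[ProteinRecord] = []
    truth_runs: list[PlantedRun] = []
    truth_ppg: list[tuple[int, int]] = []
    lengths: list[int] = []
    free_positions: list[int] = []

    for i in range(spec.n_proteins):
        rng = _rng(spec.seed, 1, i)
        length = _sample_length(rng, spec.length)
        runs_here = per_protein_runs.get(i, [])
        ppg_here = per_protein_ppg.get(i, 0)
        footprint = sum(n + 2 for _, n in runs_here) + ppg_here * 5
        if footprint > length:
            raise ValueError(
                f"protein {i}: planted footprint {footprint} exceeds length {length}; "
                "spec is infeasible"
            )
        seq = rng.choice(letters, size=length, p=probs).astype("<U1")
        occupied = np.zeros(length, dtype=bool)
        reserved = 0

        def place(span: int) -> int:
            for _ in range(_PLACEMENT_RETRIES):
                start = int(rng.integers(0, length - span + 1))
                lo = max(0, start - 1)
                hi = min(length, start + span + 1)
                if not occupied[lo:hi].any():
                    occupied[lo:hi] = True
                    return start
            raise ValueError(
                f"protein {i}: could not place a plant of span {span} after "
                f"{_PLACEMENT_RETRIES} attempts; spec is too dense"
            )

        # Longest plants first: improves packing without biasing positions.
        for residue, n in sorted(runs_here, key=lambda rn: -rn[1]):
            start = place(n)
            seq[start : start + n] = residue
            if start > 0:
                seq[start - 1] = _draw_excluding(rng, letters, probs, {residue})
                reserved += 1
            if start + n < length:
                right_excl = {residue, "G"} if residue == "P" else {residue}
                seq[start + n] = _draw_excluding(rng, letters, probs, right_excl)
                reserved += 1
            reserved += n
            truth_runs.append(
                PlantedRun(protein_index=i, residue=residue, start=start, length=n)
            )
        for _ in range(ppg_here):
            start = place(3)
            seq[start : start + 3] = ["P", "P", "G"]
            if start > 0:
                seq[start - 1] = _draw_excluding(rng, letters, probs, {"P"})
                reserved += 1
            if start + 3 < length:
                seq[start + 3] = _draw_excluding(rng, letters, probs, {"P"})
                reserved += 1
            reserved += 3
            truth_ppg.append((i, start))

        records.append(
            ProteinRecord(
                protein_id=f"SYN{i:05d}",
                gene_id=f"SYNG{i:05d}",
                description="synthetic protein",
                sequence="".join(seq),
            )
        )
        lengths.append(length)
        free_positions.append(length - reserved)

    truth = GroundTruth(
        protein_lengths=tuple(lengths),
        planted_runs=tuple(truth_runs),
        ppg_positions=tuple(truth_ppg),
        free_positions=tuple(free_positions),
    )
    return records, truth


@dataclass(frozen=True)
class ExpectedTotals:
    """Closed-form expected proteome totals for a synthetic spec."""

    ppp_units: float
    ppg: float
    prolines: float
    total_aa: int

    @property
    def ppp_freq_per_1e4(self) -> float:
        return self.ppp_units / self.total_aa * 1e4

    @property
    def ppg_freq_per_1e4(self) -> float:
        return self.ppg / self.total_aa * 1e4


def _expected_background_units(L_free: int, n_segments: int, p: float) -> float:
    """Expected Σ⌊n/3⌋ over maximal runs in i.i.d. background.

    For a single i.i.d. segment of length ℓ, the expected number of maximal
    runs of length exactly n is (ℓ−n−1)(1−p)²pⁿ + 2(1−p)pⁿ for n < ℓ.
    Summed over segments the linear term depends only on the total free
    length and the segment count; segments shorter than n are not
    special-cased (their over-counted terms are negligible for the run
    lengths that matter, pⁿ being tiny).
    """
    if p <= 0.0 or L_free <= 0:
        return 0.0
    total = 0.0
    q = 1.0 - p
    n = 3
    while n <= L_free:
        p_n = p**n
        if p_n < 1e-18:
            break
        e_n = max(L_free - n_segments * (n + 1), 0) * q * q * p_n
        e_n += 2 * n_segments * q * p_n
        total += (n // 3) * e_n
        n += 1
    return total


def expected_frequencies(
    spec: SyntheticProteomeSpec, truth: GroundTruth
) -> ExpectedTotals:
    """Expected proteome totals: planted contribution plus background.

    Background expectations use the exact i.i.d. maximal-run formula per
    protein, with the planted footprint removed from the free length and
    each plant splitting the background into an extra segment.  Exact for
    plant-free proteins; with plants the residual error from short-segment
    edge effects is far below Monte-Carlo fluctuation at realistic
    compositions (the stated check is a 5-sigma band over repeated seeds).
    """
    p_pro = spec.composition["P"]
    p_gly = spec.composition["G"]
    plants_per_protein: dict[int, int] = {}
    for run in truth.planted_runs:
        plants_per_protein[run.protein_index] = (
            plants_per_protein.get(run.protein_index, 0) + 1
        )
    for idx, _ in truth.ppg_positions:
        plants_per_protein[idx] = plants_per_protein.get(idx, 0) + 1

    units = float(truth.planted_units)
    ppg = float(truth.planted_ppg)
    prolines = float(truth.planted_prolines)
    for i, _length in enumerate(truth.protein_lengths):
        free = truth.free_positions[i]
        segments = plants_per_protein.get(i, 0) + 1
        units += _expected_background_units(free, segments, p_pro)
        ppg += max(free - 2 * segments, 0) * p_pro * p_pro * p_gly
        prolines += free * p_pro
    return ExpectedTotals(
        ppp_units=units,
        ppg=ppg,
        prolines=prolines,
        total_aa=sum(truth.protein_lengths),
    )


@dataclass(frozen=True)
class SyntheticOrthologSet:
    """Synthetic pairwise ortholog tables with designed pool membership.

    ``tables`` maps each comparator species to the pairwise (focal,
    comparator) record list; ``pool_truth`` maps pool id to the designed
    focal gene membership; ``pool_comparators`` maps pool id to the nested
    comparator tuple that defines it.
    """

    focal: str
    comparators: tuple[str, ...]
    tables: Mapping[str, tuple[OrthologRecord, ...]]
    pool_truth: Mapping[int, frozenset[str]]
    pool_comparators: Mapping[int, tuple[str, ...]]


def generate_ortholog_tables(
    species: Sequence[str],
    shared_fractions: Mapping[int, float],
    genes_per_species: int,
    seed: int = 0,
) -> SyntheticOrthologSet:
    """Build pairwise tables whose pool round-trip is known by design.

    ``species[0]`` is the focal species; with k comparators, pool ``j``
    (j = 1..k) is defined by the comparator suffix ``species[j:]`` so the
    comparator sets nest and pools must nest.  ``shared_fractions[j]`` is
    the designed fraction of focal genes in pool ``j``; feasible nesting
    requires non-increasing fractions from pool k down to pool 1.  Focal
    genes outside a pairwise share, and their comparator partners, receive
    random decoy scores strictly below 1.0.
    """
    species = list(species)
    if len(species) < 2:
        raise ValueError("need a focal species plus at least one comparator")
    focal, comparators = species[0], tuple(species[1:])
    k = len(comparators)
    fractions = {int(j): float(shared_fractions[j]) for j in range(1, k + 1)}
    for j, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"shared fraction for pool {j} must lie in [0, 1], got {f}")
    for j in range(1, k):
        if fractions[j] > fractions[j + 1] + 1e-12:
            raise ValueError(
                "infeasible nesting: shared fractions must be non-increasing "
                f"from pool {k} down to pool 1 (pool {j} > pool {j + 1})"
            )
    n_pool = {j: int(round(fractions[j] * genes_per_species)) for j in fractions}
    genes = [f"{focal}_g{i:05d}" for i in range(genes_per_species)]

    rng = _rng(seed, 7)
    tables: dict[str, tuple[OrthologRecord, ...]] = {}
    for j, comp in enumerate(comparators, start=1):
        # Focal gene i is shared with comparator j iff i < max over pools
        # containing this comparator (pools 1..j), i.e. i < n_pool[j].
        n_shared = n_pool[j]
        rows: list[OrthologRecord] = []
        for i, gene in enumerate(genes):
            cluster = f"{focal}-{comp}-c{i:05d}"
            bitscore = float(np.round(rng.uniform(100, 2000), 1))
            if i < n_shared:
                focal_score = comp_score = 1.0
            else:
                focal_score = float(np.round(rng.uniform(0.05, 0.95), 3))
                comp_score = float(np.round(rng.uniform(0.05, 0.95), 3))
            rows.append(
                OrthologRecord(
                    cluster_id=cluster,
                    species=focal,
                    gene_id=gene,
                    inparalog_score=focal_score,
                    bitscore=bitscore,
                )
            )
            rows.append(
                OrthologRecord(
                    cluster_id=cluster,
                    species=comp,
                    gene_id=f"{comp}_g{i:05d}",
                    inparalog_score=comp_score,
                    bitscore=bitscore,
                )
            )
        tables[comp] = tuple(rows)

    pool_truth = {
        j: frozenset(genes[: n_pool[j]]) for j in range(1, k + 1)
    }
    pool_comparators = {j: tuple(comparators[j - 1 :]) for j in range(1, k + 1)}
    return SyntheticOrthologSet(
        focal=focal,
        comparators=comparators,
        tables=tables,
        pool_truth=pool_truth,
        pool_comparators=pool_comparators,
    )
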