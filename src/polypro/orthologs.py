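"""InParanoid-style pairwise ortholog tables and nested ortholog pools.

Pairwise ortholog clusters arrive as "SQLtable"-layout TSV files (columns:
cluster id, bitscore, species, inparalog score, gene id).  Only genes with
an inparalog score of exactly 1.0 — the seed orthologs of each cluster —
are retained.  A *pool* for a focal species is the intersection of its
seed-ortholog gene sets across a set of comparator species: pool 1 uses
four comparators (genes shared across all five species, the oldest), down
to pool 4 with a single comparator (e.g. mouse–human only, the newest).
Nested comparator sets therefore give nested pools.

Orthology is taken per pairwise table only; no transitive closure across
species is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from polypro.scanner import ProteinMotifProfile
from polypro.stats import LengthStats, ProteomeSummary, length_stats, summarize_proteome

__all__ = [
    "OrthologRecord",
    "OrthologTableError",
    "OrthologPool",
    "PoolStatistics",
    "parse_ortholog_table",
    "filter_seed_orthologs",
    "build_pool",
    "pool_statistics",
    "write_ortholog_table",
]

#: Column order of the InParanoid "SQLtable" layout.
SQLTABLE_COLUMNS = ("cluster_id", "bitscore", "species", "inparalog_score", "gene_id")


class OrthologTableError(ValueError):
    """Raised for malformed ortholog tables, with the offending line number."""


@dataclass(frozen=True)
class OrthologRecord:
    """One gene's membership in one pairwise ortholog cluster."""

    cluster_id: str
    species: str
    gene_id: str
    inparalog_score: float
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inparalog_score <= 1.0:
            raise ValueError(
                f"inparalog score must lie in [0, 1], got {self.inparalog_score}"
            )
        if self.bitscore < 0:
            raise ValueError(f"bitscore must be non-negative, got {self.bitscore}")


def parse_ortholog_table(
    path: str | Path, species_a: str, species_b: str
) -> list[OrthologRecord]:
    """Parse one pairwise ortholog table in SQLtable layout.

    A header line starting with ``cluster_id`` is permitted and skipped
    (raw InParanoid dumps carry none).  Every ``species`` cell must equal
    ``species_a`` or ``species_b``; scores must parse as reals in [0, 1].
    Errors name the offending line number.
    """
    path = Path(path)
    expected = {species_a, species_b}
    records: list[OrthologRecord] = []
    seen: set[tuple[str, str, str]] = set()
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "cluster_id":
                continue
            if len(fields) < 5:
                raise OrthologTableError(
                    f"{path.name}:{lineno}: expected 5 tab-separated columns "
                    f"{SQLTABLE_COLUMNS}, got {len(fields)}"
                )
            cluster_id, bitscore_s, species, score_s, gene_id = fields[:5]
            if species not in expected:
                raise OrthologTableError(
                    f"{path.name}:{lineno}: unknown species {species!r}, "
                    f"expected one of {sorted(expected)}"
                )
            try:
                score = float(score_s)
                bitscore = float(bitscore_s)
            except ValueError as exc:
                raise OrthologTableError(
                    f"{path.name}:{lineno}: unparseable score: {exc}"
                ) from None
            if not 0.0 <= score <= 1.0 or not math.isfinite(score):
                raise OrthologTableError(
                    f"{path.name}:{lineno}: inparalog score {score} outside [0, 1]"
                )
            key = (cluster_id, species, gene_id)
            if key in seen:
                raise OrthologTableError(
                    f"{path.name}:{lineno}: duplicate (cluster, species, gene) {key}"
                )
            seen.add(key)
            records.append(
                OrthologRecord(
                    cluster_id=cluster_id,
                    species=species,
                    gene_id=gene_id,
                    inparalog_score=score,
                    bitscore=bitscore,
                )
            )
    return records


def filter_seed_orthologs(
    records: Iterable[OrthologRecord],
    score_tolerance: float = 0.0,
    require_both_sides: bool = False,
) -> dict[str, set[str]]:
    """Per species, the genes whose inparalog score equals 1.0.

    Scores are compared exactly by default (InParanoid writes exact
    decimals); ``score_tolerance`` admits ``score >= 1 - tolerance`` for
    tables with floating-point artifacts.  With ``require_both_sides`` a
    gene only qualifies if its cluster also contains a qualifying gene of
    the other species.  A gene qualifying in several clusters appears
    once (set semantics).
    """
    records = list(records)
    cutoff = 1.0 - score_tolerance

    def qualifies(r: OrthologRecord) -> bool:
        return r.inparalog_score >= cutoff

    good_clusters_by_species: dict[str, set[str]] = {}
    if require_both_sides:
        for r in records:
            if qualifies(r):
                good_clusters_by_species.setdefault(r.species, set()).add(r.cluster_id)

    out: dict[str, set[str]] = {}
    for r in records:
        out.setdefault(r.species, set())
        if not qualifies(r):
            continue
        if require_both_sides:
            others = set().union(
                *(
                    clusters
                    for sp, clusters in good_clusters_by_species.items()
                    if sp != r.species
                ),
            ) if len(good_clusters_by_species) > 1 else set()
            if r.cluster_id not in others:
                continue
        out[r.species].add(r.gene_id)
    return out


@dataclass(frozen=True)
class OrthologPool:
    """A focal species' genes shared (score 1.0) across a comparator set."""

    focal_species: str
    comparator_species: tuple[str, ...]
    pool_id: int
    member_gene_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.member_gene_ids)


def build_pool(
    focal: str,
    pairwise_sets: Mapping[str, set[str] | frozenset[str]],
    pool_id: int,
    comparators: Sequence[str] | None = None,
) -> OrthologPool:
    """Intersect the focal-side seed-ortholog sets over the comparators.

    ``pairwise_sets`` maps each comparator species to the focal species'
    qualifying gene set from that pairwise comparison.  ``comparators``
    defaults to every key of the mapping; naming a comparator with no
    corresponding set is a hard error.
    """
    if comparators is None:
        comparators = sorted(pairwise_sets)
    comparators = tuple(comparators)
    if not comparators:
        raise ValueError("a pool needs at least one comparator species")
    missing = [c for c in comparators if c not in pairwise_sets]
    if missing:
        raise ValueError(f"missing pairwise gene set for comparator(s): {missing}")
    members = frozenset.intersection(
        *(frozenset(pairwise_sets[c]) for c in comparators)
    )
    return OrthologPool(
        focal_species=focal,
        comparator_species=comparators,
        pool_id=pool_id,
        member_gene_ids=members,
    )


@dataclass(frozen=True)
class PoolStatistics:
    """Proteome-style summary and length statistics of one pool's members."""

    pool: OrthologPool
    summary: ProteomeSummary
    lengths: LengthStats


def pool_statistics(
    pool: OrthologPool, profiles: Mapping[str, ProteinMotifProfile]
) -> PoolStatistics:
    """Apply the proteome summary/length formulas to the pool members only.

    ``profiles`` maps gene ids to motif profiles; a member without a
    profile is a hard error listing the missing genes, and an empty pool
    is an error (its frequencies are undefined).
    """
    if not pool.member_gene_ids:
        raise ValueError(
            f"pool {pool.pool_id} of {pool.focal_species} is empty; "
            "pool frequencies are undefined"
        )
    missing = sorted(g for g in pool.member_gene_ids if g not in profiles)
    if missing:
        raise KeyError(
            f"pool {pool.pool_id} of {pool.focal_species}: no motif profile "
            f"for member gene(s) {missing}"
        )
    member_profiles = [profiles[g] for g in sorted(pool.member_gene_ids)]
    label = f"{pool.focal_species}:pool{pool.pool_id}"
    return PoolStatistics(
        pool=pool,
        summary=summarize_proteome(member_profiles, label),
        lengths=length_stats(member_profiles),
    )


def write_ortholog_table(
    records: Iterable[OrthologRecord], path: str | Path, header: bool = True
) -> None:
    """Write records as a SQLtable-layout TSV (header row by default)."""
    path = Path(path)
    with path.open("w") as handle:
        if header:
            handle.write("\t".join(SQLTABLE_COLUMNS) + "\n")
        for r in records:
            handle.write(
                f"{r.cluster_id}\t{r.bitscore:g}\t{r.species}\t"
                f"{r.inparalog_score:g}\t{r.gene_id}\n"
            )
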