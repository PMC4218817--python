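"""TSV report emission.

All tables are TSV (gene descriptions contain commas), UTF-8, Unix
newlines, with a mandatory header row.  Rounding to the reported precision
happens only here, at serialization; every aggregate is carried at full
precision upstream.  Layouts mirror the classic comparative tables: a
run-length histogram per species ("table1"), proteome totals and
calibrated frequencies ("table2"), unit-threshold gene groups, per-protein
censuses and per-pool statistics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from polypro.orthologs import PoolStatistics
from polypro.scanner import STANDARD_AA, ProteinMotifProfile
from polypro.stats import (
    AAComposition,
    GeneGroup,
    LengthStats,
    ProteomeSummary,
    RUN_BUCKETS,
    RunLengthTable,
    round_half_up,
)

__all__ = [
    "protein_table",
    "summary_table",
    "table1",
    "groups_table",
    "length_table",
    "composition_table",
    "pool_table",
    "write_tsv",
]


def _fmt(value: float, ndigits: int | None) -> float:
    return value if ndigits is None else round_half_up(value, ndigits)


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def protein_table(profiles: Sequence[ProteinMotifProfile]) -> pd.DataFrame:
    """Per-protein census: one row per protein, runs semicolon-joined."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "protein_id": p.protein_id,
                "gene_id": p.gene_id,
                "description": p.description,
                "length": p.length,
                "ppp_units": p.ppp_units,
                "ppg_count": p.ppg_count,
                "proline_count": p.proline_count,
                "run_lengths": ";".join(str(r.length) for r in p.runs),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "gene_id",
            "description",
            "length",
            "ppp_units",
            "ppg_count",
            "proline_count",
            "run_lengths",
        ],
    )


def summary_table(
    summaries: Sequence[ProteomeSummary], precision: int | None = 2
) -> pd.DataFrame:
    """Proteome totals and frequencies, one row per species ("table2")."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "species": s.species_label,
                "n_orfs": s.n_orfs,
                "total_ppp_units": s.total_ppp_units,
                "total_ppg": s.total_ppg,
                "total_proline": s.total_proline,
                "total_aa": s.total_aa,
                "ppp_freq_per_1e4": _fmt(s.ppp_freq_per_1e4, precision),
                "ppg_freq_per_1e4": _fmt(s.ppg_freq_per_1e4, precision),
                "proline_pct": _fmt(s.proline_pct, precision),
            }
        )
    return pd.DataFrame(rows)


def table1(
    tables: Mapping[str, RunLengthTable], precision: int | None = 1
) -> pd.DataFrame:
    """Run-length histogram rows, one per species."""
    rows = []
    for label, t in tables.items():
        row: dict = {"species": label}
        for n in RUN_BUCKETS:
            row[f"{n}P"] = t.counts[n]
        row[">10P"] = t.overflow_count
        row["total"] = t.total_runs
        row["pct_3P"] = _fmt(t.pct_3p, precision)
        row["pct_3P_defined"] = t.pct_3p_defined
        rows.append(row)
    return pd.DataFrame(rows)


def groups_table(
    groups_by_species: Mapping[str, Sequence[GeneGroup]], precision: int | None = 1
) -> pd.DataFrame:
    """Unit-threshold gene groups, ordered by species, motif, threshold."""
    rows = []
    for label, groups in groups_by_species.items():
        for g in sorted(groups, key=lambda g: (g.motif, g.threshold)):
            rows.append(
                {
                    "species": label,
                    "motif": g.motif,
                    "threshold": g.threshold,
                    "n_proteins": g.count,
                    "percent": _fmt(g.pct_of_proteome, precision),
                }
            )
    return pd.DataFrame(rows)


def length_table(
    stats_by_label: Mapping[str, LengthStats], precision: int | None = 1
) -> pd.DataFrame:
    """Box-plot length statistics, one row per labelled protein set."""
    rows = []
    for label, s in stats_by_label.items():
        rows.append(
            {
                "group": label,
                "n": s.n,
                "min": s.min,
                "q1": _fmt(s.q1, precision),
                "median": _fmt(s.median, precision),
                "mean": _fmt(s.mean, precision),
                "q3": _fmt(s.q3, precision),
                "max": s.max,
            }
        )
    return pd.DataFrame(rows)


def composition_table(
    comp_by_species: Mapping[str, AAComposition], precision: int | None = None
) -> pd.DataFrame:
    """20-residue counts, frequencies and triplet units per species."""
    rows = []
    for label, comp in comp_by_species.items():
        for residue in list(STANDARD_AA) + ["other"]:
            rows.append(
                {
                    "species": label,
                    "residue": residue,
                    "count": comp.counts[residue],
                    "frequency": _fmt(comp.frequencies[residue], precision),
                    "triplet_units": comp.triplet_unit_totals.get(residue, 0),
                    "triplet_unit_frequency": _fmt(
                        comp.triplet_unit_frequencies.get(residue, 0.0), precision
                    ),
                }
            )
    return pd.DataFrame(rows)


def pool_table(
    stats: Sequence[PoolStatistics], precision: int | None = 2
) -> pd.DataFrame:
    """Per-pool member counts, length statistics and motif frequencies."""
    rows = []
    for ps in stats:
        rows.append(
            {
                "focal_species": ps.pool.focal_species,
                "pool_id": ps.pool.pool_id,
                "comparators": ",".join(ps.pool.comparator_species),
                "n_genes": len(ps.pool),
                "mean_length": _fmt(ps.lengths.mean, precision),
                "median_length": _fmt(ps.lengths.median, precision),
                "q1_length": _fmt(ps.lengths.q1, precision),
                "q3_length": _fmt(ps.lengths.q3, precision),
                "ppp_freq_per_1e4": _fmt(ps.summary.ppp_freq_per_1e4, precision),
                "ppg_freq_per_1e4": _fmt(ps.summary.ppg_freq_per_1e4, precision),
            }
        )
    return pd.DataFrame(rows)
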