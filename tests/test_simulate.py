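"""Synthetic proteome generation: exact plant recovery, determinism,
closed-form expectations and ortholog-table round-trips."""

import numpy as np
import pytest

from polypro.io import write_fasta
from polypro.orthologs import (
    build_pool,
    filter_seed_orthologs,
    parse_ortholog_table,
    write_ortholog_table,
)
from polypro.scanner import scan_protein
from polypro.simulate import (
    SyntheticProteomeSpec,
    expected_frequencies,
    generate_ortholog_tables,
    generate_proteome,
    uniform_composition,
)


def proline_free_composition():
    return {aa: 1 / 19 for aa in "ACDEFGHIKLMNQRSTVWY"}


class TestSpecValidation:
    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticProteomeSpec(n_proteins=1, composition={"A": 0.5})

    def test_planted_run_below_three_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            SyntheticProteomeSpec(n_proteins=1, planted_runs=(("P", 2, 1),))

    def test_infeasible_plants_error(self):
        spec = SyntheticProteomeSpec(
            n_proteins=1, length=20, planted_runs=(("P", 10, 3),), seed=0
        )
        with pytest.raises(ValueError, match="infeasible|dense"):
            generate_proteome(spec)


class TestExactRecovery:
    def test_planted_runs_recovered_exactly_without_background_proline(self):
        spec = SyntheticProteomeSpec(
            n_proteins=10,
            length=200,
            composition=proline_free_composition(),
            planted_runs=(("P", 5, 3), ("P", 3, 4)),
            ppg_plants=5,
            seed=7,
        )
        records, truth = generate_proteome(spec)
        lengths = []
        total_ppg = 0
        total_prolines = 0
        for i, record in enumerate(records):
            profile = scan_protein(record)
            planted = [(r.start, r.length) for r in truth.runs_for_protein(i)]
            observed = [(r.start, r.length) for r in profile.runs]
            assert observed == planted
            lengths.extend(r.length for r in profile.runs)
            total_ppg += profile.ppg_count
            total_prolines += profile.proline_count
        assert sorted(lengths, reverse=True) == [5, 5, 5, 3, 3, 3, 3]
        assert total_ppg == truth.planted_ppg == 5
        assert total_prolines == truth.planted_prolines

    def test_no_plants_no_proline_background_scans_empty(self):
        spec = SyntheticProteomeSpec(
            n_proteins=5, length=100, composition=proline_free_composition(), seed=3
        )
        records, truth = generate_proteome(spec)
        for record in records:
            profile = scan_protein(record)
            assert profile.ppp_units == 0
            assert profile.proline_count == 0
        assert truth.planted_units == 0

    def test_generic_residue_plants_recovered(self):
        spec = SyntheticProteomeSpec(
            n_proteins=4,
            length=150,
            composition={aa: 1 / 19 for aa in "ACDEFGHIKLMNPRSTVWY"},  # no Q
            planted_runs=(("Q", 7, 3),),
            seed=11,
        )
        records, truth = generate_proteome(spec)
        observed = sum(
            scan_protein(r).triplet_units["Q"] for r in records
        )
        assert observed == truth.planted_units == 3 * 2


class TestDeterminism:
    def test_same_seed_byte_identical_fasta(self, tmp_path):
        spec = SyntheticProteomeSpec(
            n_proteins=10, length=200, planted_runs=(("P", 5, 3),), seed=7
        )
        paths = []
        for name in ("a.fasta", "b.fasta"):
            records, _ = generate_proteome(spec)
            path = tmp_path / name
            write_fasta(records, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seeds_differ(self):
        rec_a, _ = generate_proteome(SyntheticProteomeSpec(n_proteins=3, length=80, seed=1))
        rec_b, _ = generate_proteome(SyntheticProteomeSpec(n_proteins=3, length=80, seed=2))
        assert [r.sequence for r in rec_a] != [r.sequence for r in rec_b]


class TestExpectations:
    def test_plants_only_expectation_is_exact(self):
        spec = SyntheticProteomeSpec(
            n_proteins=6,
            length=120,
            composition=proline_free_composition(),
            planted_runs=(("P", 6, 2), ("P", 3, 3)),
            ppg_plants=2,
            seed=0,
        )
        _, truth = generate_proteome(spec)
        exp = expected_frequencies(spec, truth)
        assert exp.ppp_units == truth.planted_units == 7
        assert exp.ppg == truth.planted_ppg == 2

    def test_duplicating_the_spec_doubles_totals_not_frequencies(self):
        base = SyntheticProteomeSpec(n_proteins=20, length=250, seed=5)
        double = SyntheticProteomeSpec(n_proteins=40, length=250, seed=5)
        exp1 = expected_frequencies(base, generate_proteome(base)[1])
        exp2 = expected_frequencies(double, generate_proteome(double)[1])
        assert exp2.ppp_units == pytest.approx(2 * exp1.ppp_units)
        assert exp2.total_aa == 2 * exp1.total_aa
        assert exp2.ppp_freq_per_1e4 == pytest.approx(exp1.ppp_freq_per_1e4)

    def test_background_totals_within_five_sigma_of_closed_form(self):
        """Monte-Carlo check of the analytic maximal-run expectation:
        observed unit/PPG/proline totals over 20 seeds stay within 5σ of
        the closed form (standard error of the seed mean)."""
        n_seeds = 20
        units, ppgs, prolines = [], [], []
        expected = None
        for seed in range(n_seeds):
            spec = SyntheticProteomeSpec(
                n_proteins=40, length=300, composition=uniform_composition(), seed=seed
            )
            records, truth = generate_proteome(spec)
            if expected is None:
                expected = expected_frequencies(spec, truth)
            profiles = [scan_protein(r) for r in records]
            units.append(sum(p.ppp_units for p in profiles))
            ppgs.append(sum(p.ppg_count for p in profiles))
            prolines.append(sum(p.proline_count for p in profiles))
        for observed, mean_expected in (
            (units, expected.ppp_units),
            (ppgs, expected.ppg),
            (prolines, expected.prolines),
        ):
            sem = np.std(observed, ddof=1) / np.sqrt(n_seeds)
            assert abs(np.mean(observed) - mean_expected) < 5 * sem


class TestOrthologTables:
    def test_designed_pool_sizes_recovered_exactly(self, tmp_path):
        ortho = generate_ortholog_tables(
            ["F", "B1", "B2", "B3", "B4"],
            shared_fractions={1: 0.1, 2: 0.2, 3: 0.4, 4: 0.6},
            genes_per_species=100,
            seed=13,
        )
        # Round-trip through TSV files and the parser.
        sets = {}
        for comp, table in ortho.tables.items():
            path = tmp_path / f"{comp}.tsv"
            write_ortholog_table(table, path)
            records = parse_ortholog_table(path, "F", comp)
            sets[comp] = filter_seed_orthologs(records)["F"]
        pools = {}
        for pid, comps in ortho.pool_comparators.items():
            pools[pid] = build_pool("F", sets, pid, comparators=comps)
            assert pools[pid].member_gene_ids == ortho.pool_truth[pid]
        assert [len(pools[p]) for p in (1, 2, 3, 4)] == [10, 20, 40, 60]
        assert (
            pools[1].member_gene_ids
            <= pools[2].member_gene_ids
            <= pools[3].member_gene_ids
            <= pools[4].member_gene_ids
        )

    def test_full_sharing_puts_every_gene_in_every_pool(self):
        ortho = generate_ortholog_tables(
            ["F", "B1", "B2"], {1: 1.0, 2: 1.0}, genes_per_species=10, seed=0
        )
        assert all(len(m) == 10 for m in ortho.pool_truth.values())

    def test_zero_pool1_fraction(self):
        ortho = generate_ortholog_tables(
            ["F", "B1", "B2"], {1: 0.0, 2: 0.5}, genes_per_species=10, seed=0
        )
        assert ortho.pool_truth[1] == frozenset()
        assert len(ortho.pool_truth[2]) == 5

    def test_infeasible_nesting_rejected(self):
        with pytest.raises(ValueError, match="nesting"):
            generate_ortholog_tables(
                ["F", "B1", "B2"], {1: 0.9, 2: 0.1}, genes_per_species=10, seed=0
            )
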