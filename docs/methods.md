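# Methods

## Motif model

The quantum of polyproline content is the *repeat unit*: a maximal run of
*n* ≥ 3 identical residues contributes ⌊*n*/3⌋ units, equivalently the
number of disjoint triplets that fit inside the run.  Maximality follows
the `XPnX` convention — the run's flanks hold a different residue — with
sequence boundaries treated as non-matching flanks, so terminal runs count.
The alternative (requiring literal flanking residues) would silently drop
every protein beginning or ending in a repeat; nothing in the unit rule
justifies that loss.

PPG is the exact tripeptide Pro-Pro-Gly counted without overlap.  Because
PPG cannot overlap itself (first and last residues differ), the
non-overlapping count equals the number of match positions; the test suite
proves this equivalence property on random strings.  PPP units and PPG are
counted by **independent** scans of the same sequence: `PPPPG` contributes
one PPP unit *and* one PPG.  No published exclusion rule exists for PPG
trigrams whose prolines sit inside a longer polyproline run, and the two
totals are reported as separate columns; users needing the exclusive
variant can subtract runs' glycine-flank matches from the per-protein
table.

Ambiguity letters (X, B, Z, U, O) count toward protein length — the
frequency denominators are total residue counts — but never extend a run:
`PPXPP` holds two runs of length 2 and zero units.

## Dataset preparation

FASTA input is normalized (uppercase, one trailing `*` stripped); internal
stops or non-letter characters reject the record outright rather than being
cleaned, since they indicate pseudogene leakage or corrupt translations.
With Ensembl-style headers, entries whose biotype names a pseudogene or
transposable element are dropped.  Transcript-level proteomes are reduced
to the longest protein per gene; equal-length ties keep the
lexicographically smallest protein id, a deterministic choice under any
input ordering.  Proteins lacking a gene assignment are treated as their
own gene (`gene_id = protein_id`).

## Aggregation conventions

* Integer totals (units, PPG, prolines, residues) are exact sums; derived
  frequencies (units per 10⁴ residues, proline %) are properties of the
  stored integers and carried at full precision.  Rounding — half-up, ties
  away from zero — happens only at table serialization: frequencies to 2
  decimals, percentages to 1, configurable and disabled by
  `--full-precision`.
* The run-length histogram uses explicit buckets 3…10 plus a `>10` bucket
  (lengths ≥ 11).  The exact lengths behind `>10` are preserved alongside
  the table because the bucket count alone under-determines the unit
  total; recomputing units from a histogram therefore requires them, and
  the pipeline checks the resulting conservation identity
  `units_from_table(run_length_table(P)) == summarize(P).total_ppp_units`
  on every proteome.
* A repeat-free proteome yields a histogram whose "3P as % of total" is
  reported as 0 with an explicit undefined flag instead of raising, so
  multi-species batch runs survive repeat-free inputs.
* Box-plot length statistics use linear interpolation between closest
  order statistics for the quartiles (numpy's default percentile method);
  box-plot conventions differ between tools, so the method is echoed in
  each run's metadata file.  The mean is exact.
* Unit-threshold gene groups (≥1, ≥2, ≥3 units of PPP, PPG, or any
  single-residue triplet) nest by construction, and percentages are taken
  over the proteome's gene count.

## Ortholog pools

Pairwise InParanoid-style tables (SQLtable layout: cluster id, bitscore,
species, inparalog score, gene id) are filtered to genes with inparalog
score **exactly 1.0** — the cluster seeds — compared exactly by default
because InParanoid writes exact decimals; a logged tolerance option exists
for tables with floating-point artifacts.  The filter applies to the focal
species' side; an option additionally requires a score-1.0 partner on the
other side of the cluster.  A pool is the plain set intersection of the
focal species' seed sets across its comparators; nested comparator sets
give nested pools (pool 1 ⊆ pool 2 ⊆ pool 3 ⊆ pool 4), and intersection is
order-independent.  No transitive closure across species is attempted —
orthology is taken per pairwise table, mirroring the pairwise-intersection
construction.  A pool member without a scanned profile is a hard error
listing the missing genes; an empty pool has undefined frequencies and is
likewise an error rather than a silent zero.

## Synthetic data

The generator emulates the statistical structure the pipeline measures,
not evolution: background residues are drawn i.i.d. from a configurable
composition (default uniform, putting proline at 5% — inside the 4.3–6.3%
range real proteomes span from bacteria to human), and repeat runs of
exact lengths are planted at random non-overlapping positions.  Flank
positions of each plant are redrawn excluding the planted residue (and,
to the right of a proline run, glycine), so every planted run is maximal
at exactly its planted length and no accidental PPG forms at a plant
boundary.  Placement is rejection sampling against an occupancy mask that
includes the flanks, with a retry cap (1000) before declaring the spec
infeasible.  One global seed drives a per-protein stream keyed by
`(seed, protein index)`, so any record is reproducible independently of
generation order and equal seeds give byte-identical FASTA.

With the background probability of the planted residue at zero, the
scanner must recover the plants exactly, protein by protein.  With a
nonzero background, expected totals come from the exact i.i.d. formula for
the number of maximal runs of length *n* in a segment of length ℓ,
(ℓ−n−1)(1−p)²pⁿ + 2(1−p)pⁿ, summed over n ≥ 3 weighted by ⌊n/3⌋; plants
remove their footprint from the free length and split the background into
segments.  The aggregation over segments keeps only the total free length
and segment count, so segments shorter than *n* are not special-cased;
this residual (and the truncation at pⁿ < 10⁻¹⁸) is far below the
Monte-Carlo fluctuation the checks allow — observed totals over 20 seeds
must lie within 5σ (standard error of the seed mean) of the expectation.

Synthetic ortholog tables encode designed nested pool memberships through
their score-1.0 structure (decoy genes receive random scores strictly
below 1.0 on both sides), so pool construction is checked by exact
round-trip through file serialization and parsing.

What passing these tests does **not** show about real data: real proteomes
are not i.i.d. — they contain low-complexity regions, compositional
heterogeneity between proteins, and correlated repeat expansions — and
real ortholog tables carry many-to-many clusters and id-namespace
mismatches.  The synthetic checks validate the measurement machinery, not
any biological claim.

## Reference arithmetic and problem sizes

The published comparative tables are used as *inputs* to verify internal
arithmetic: the E. coli run-length row (90, 6, 2, 0, 0, 1, 0, 0, 0) must
total 99 runs with 90.9% triple-prolines and imply exactly 100 PPP units;
the published integer totals must reproduce the published frequencies
(0.76/10⁴ and 4.44% proline for E. coli, 8.28/10⁴ for human) at half-up
rounding.  Whole-proteome totals (e.g. 597 yeast PPP units) depend on the
specific database releases originally used and are deliberately not
asserted; users who supply those releases can reproduce them with
`polypro table2 --longest-only`.

The acceptance script re-derives the unit rule on single runs of 3 and 8
prolines and the E. coli unit total by planting the published run multiset
(99 runs) into a 50-protein × 400-residue proline-free synthetic proteome
and running the full scan → histogram → unit pipeline.  Test-suite
simulations use 10–40 proteins of 200–300 residues over 20 seeds — sizes
chosen so the 5σ statistical checks are already sharp at desk scale.

## Known limitations

* Exact-trigram and homopolymer logic only: no PSSM or fuzzy matching, and
  no non-consecutive proline-rich patterns (PXXP and relatives).
* The score-1.0 filter's sidedness in the original analysis is unknowable
  from the publication; both variants are provided, neither asserted.
* `expected_frequencies` assumes plants are sparse relative to protein
  length; extremely dense specs should rely on the exact-recovery mode.
* The CLI applies one gene map to every FASTA given in a single
  invocation; per-species maps require separate invocations.
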