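# polypro

A census of polyproline (PPP) and Pro-Pro-Gly (PPG) motifs — and of amino-acid
tandem repeats in general — across whole proteomes.

Consecutive prolines stall the ribosome during peptide-bond formation; the
translation factors EF-P (bacteria) and eIF5A (eukaryotes, carrying the
hypusine modification) relieve that stalling at PPP and PPG motifs.  Comparing
how often these motifs occur across proteomes — and whether they concentrate
in evolutionarily young proteins — therefore speaks to the role of eIF5A in
eukaryotic evolution.  `polypro` implements that comparative analysis as a
tested pipeline for anyone with protein FASTA files and (optionally)
InParanoid-style pairwise ortholog tables.

## The statistic

For each protein, every *maximal run* of a residue is found: a stretch of
*n* identical residues whose flanking positions (or the sequence ends) hold
a different residue.  A run of *n* ≥ 3 consecutive prolines contributes

&nbsp;&nbsp;&nbsp;&nbsp;units(*n*) = ⌊*n*/3⌋

PPP units (runs of 3–5 prolines count as one unit, 6–8 as two, …).  PPG is
counted as non-overlapping occurrences of the exact tripeptide P-P-G, by an
independent scan of the same sequence.  Proteome-level frequencies are
calibrated against proteome size:

&nbsp;&nbsp;&nbsp;&nbsp;freq = (Σ units) / (Σ residues) × 10⁴ per 10,000 amino acids.

The same triplet-unit rule applies to all 20 amino acids for the general
tandem-repeat comparison.  Ortholog *pools* are nested gene sets of a focal
species shared (InParanoid inparalog score exactly 1.0) with progressively
fewer comparator species; pool statistics apply the same formulas to the
pool members only.

## Worked example

```
$ cat demo.fasta
>vrp1-like gene:gA
MPPPPPPPPPAKPPPPPPPPLWPPPPPPAK
>collagen-like gene:gB
MGPPGAPPGQPPGAPPG
>plain gene:gC
MKLVNQHAAA

$ polypro scan --fasta demo.fasta --species demo --header-schema ensembl --out demo_out
[scan] demo: 3 proteins, 7 PPP units, 4 PPG (0.00s)

$ cat demo_out/proteins_demo.tsv
protein_id	gene_id	description	length	ppp_units	ppg_count	proline_count	run_lengths
vrp1-like	gA	gene:gA	30	7	0	23	9;8;6
collagen-like	gB	gene:gB	17	0	4	8
plain	gC	gene:gC	10	0	0	0

$ cat demo_out/summary.tsv
species	n_orfs	total_ppp_units	total_ppg	total_proline	total_aa	ppp_freq_per_1e4	ppg_freq_per_1e4	proline_pct
demo	3	7	4	31	57	1228.07	701.75	54.39
```

The first protein carries maximal proline runs of 9, 8 and 6 residues —
⌊9/3⌋ + ⌊8/3⌋ + ⌊6/3⌋ = 7 PPP units — and, its runs having no glycine
flank, no PPG.  The collagen-like protein has no run of three prolines but
four PPG tripeptides.  The summary row gives the proteome totals and the
calibrated frequencies (here enormous, as this toy proteome is 54% proline).

Other subcommands: `table1` (run-length histogram 3P…10P, >10P per species),
`table2` (totals and frequencies), `stats` (≥1/≥2/≥3-unit gene groups,
box-plot length statistics, 20-residue composition and triplet units),
`pools` (score-1.0 ortholog pools and their statistics), `simulate`
(synthetic proteomes with planted, ground-truthed repeats) and `demo`
(end-to-end pipeline on synthetic data with recovery checks).  All outputs
are TSV with a header row; `--full-precision` disables report rounding.

Real analyses start from proteome FASTA files (e.g. Ensembl `pep` dumps with
`--header-schema ensembl`, which drops pseudogene/transposon biotypes) and
usually `--longest-only` to keep one longest protein per gene.

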