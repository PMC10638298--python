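# dhmut

Identification of induced homozygous mutations in doubled-haploid (DH)
mutant populations from whole-genome genotype calls.

## The problem

EMS (ethyl methanesulfonate) mutagenesis of isolated microspores, followed
by doubled-haploid regeneration, yields plant lines that are homozygous at
every locus after a single generation — ideal for TILLING populations and
field trials. Sequencing those lines reveals two superimposed mutation
processes: *somaclonal* variation from the tissue-culture step itself, and
*EMS-induced* mutations with the canonical G/C→A/T transition signature.
`dhmut` is for researchers building or analyzing such populations: it calls
per-line induced mutations from VCFs, quantifies them per megabase of
callable genome, classifies the substitution spectrum, and separates the
EMS component from the tissue-culture background.

## The method

Per sample, genotype calls are filtered (bi-allelic SNVs only; read depth
2 ≤ DP ≤ 30; heterozygous calls discarded — DH material is homozygous
everywhere). A mutation is accepted in sample *s* at a site when

* (i) the parental state — the consensus of seed-germinated replicates of
  the same genotype, homozygous-reference where the parents are silent — is
  homozygous,
* (ii) *s* carries a valid homozygous call whose allele differs from the
  parental allele, and
* (iii) no other sample in the cohort carries a valid homozygous call for
  that allele at that site (cohort uniqueness: shared alleles are
  pre-existing variants, not per-line induced mutations).

Per-sample frequency is n / (callable Mb), with the callable genome size —
cumulative length of regions supporting a confident call — as denominator.
The induced rate is the treated-group mean minus the control-group mean:

    r_EMS = mean(r_treated) − mean(r_control)   [mutations/Mb]

Substitutions are grouped into the six strand-symmetric classes
(A/T→G/C, G/C→A/T, A/T→C/G, A/T→T/A, G/C→T/A, G/C→C/G); group spectra are
compared with a seeded permutation test. A synthetic cohort generator with
ground truth (random reference, somaclonal + EMS truth mutations,
negative-binomial depths, call errors) validates the whole chain; see
`docs/methods.md` for the model and its assumptions, and
`docs/alignment_preamble.md` for the upstream read-processing template that
produces the input VCFs for real data.

## Worked example

Simulate a cohort under the default study conditions (50 Mb genome,
2 parent replicates, 3 controls at 1.84 somaclonal mutations/Mb, 3 treated
lines adding 0.35 EMS mutations/Mb with a 90% G/C→A/T EMS spectrum) and run
the full pipeline:

```bash
dhmut run --out demo --seed 7
```

prints

```
called 600 mutations; control mean 1.8 /Mb, treated mean 2.49 /Mb, induced 0.69 /Mb
demo/manifest.json
```

i.e. 600 accepted mutations across the six regenerated samples; the control
mean recovers the simulated somaclonal background (1.80 vs 1.84 configured)
and the treated mean its background-plus-EMS sum, with the induced rate for
this single three-versus-three cohort scattering around the configured
0.35/Mb (averaging over replicate cohorts tightens it; see
`scripts/acceptance.py`). `demo/frequency.tsv` holds the per-sample detail:

```
sample_id   n_mutations_genome  callable_size  ratio_genome  n_mutations_gene  gene_region_size  ratio_gene
control_1   90                  46654416       1.93          1                 1700085           0.59
control_2   76                  46653974       1.63          3                 1700085           1.76
```

— e.g. control_1: 90 accepted mutations over 46.65 Mb callable → 1.93/Mb
genome-wide, with 1 mutation inside the 1.70 Mb of gene intervals.
`demo/spectrum.tsv` holds per-sample class counts and the G/C→A/T fraction,
and `demo/spectrum_comparison.tsv` the control-vs-treated per-class effects
with permutation p-values. The same stages are available separately as
`dhmut simulate | filter | call | stats | tally` for file-based (real-data)
workflows, and as library functions (`dhmut.analyze_callsets`, ...).

The package also bundles the published production and sequencing summary
tables of the barley DH study it emulates (`dhmut.datasets`): DH-line
tallies per genotype × dose and the per-sample mutation counts, mapped-
genome sizes and per-Mb ratios of the sequenced subset.

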