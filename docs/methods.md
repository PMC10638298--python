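# Methods

## Problem setting

Chemical mutagenesis with EMS (ethyl methanesulfonate) combined with
microspore culture produces doubled-haploid (DH) plant lines that are
homozygous at every locus after a single generation. Whole-genome sequencing
of regenerated lines then reveals two superimposed mutation processes:
*somaclonal* (tissue-culture–induced) variation, present in every
regenerated line whether or not a mutagen was applied, and *EMS-induced*
mutations, which carry a characteristic G/C→A/T transition signature from
guanine alkylation. `dhmut` identifies per-line induced homozygous mutations
from genotype calls, quantifies them per megabase of callable genome, and
decomposes the treated-line mutation rate into its tissue-culture background
and EMS components.

## Mutation identification

Input is one VCF of genotype calls per sample, all called against the same
reference. Samples carry a role: seed-germinated **parent** replicates of
the starting genotype, regenerated **controls** (microspore culture, no
EMS), and regenerated **treated** lines (culture + EMS).

Site-level filters, applied per sample per site in a fixed precedence so
every dropped call is counted once:

1. only bi-allelic SNV records are accepted (indels and symbolic alleles are
   dropped at read time);
2. the read depth must lie in the inclusive window `[min_depth, max_depth]`,
   default **2–30 reads** — the floor removes single-read artifacts, the cap
   removes collapsed-repeat pileups (missing DP is treated as depth 0 and
   therefore fails);
3. heterozygous calls are discarded: DH material is homozygous everywhere,
   so a het call is a mapping/calling artifact. Homozygous-reference calls
   are retained at this stage because they establish parental states.

A **parental baseline** is built from the filtered parent replicates: a site
enters with the allele on which all replicates holding a valid homozygous
call agree; sites with conflicting valid parent calls are flagged
unresolvable and excluded from calling in every sample (the conservative
choice — such sites cannot distinguish mutation from parental
heterogeneity). Where the parents are silent at a site (no valid call), the
parental state defaults to homozygous-reference, since both parents and
mutants were called against the same reference; `require_parent_call=True`
disables the default and skips such sites instead.

A mutation is accepted in a sample when

* (i) the parental state at the site is homozygous (explicit or default),
* (ii) the sample's call is homozygous with an allele differing from the
  parental allele (this includes back-mutations to the reference under a
  non-reference parental allele), and
* (iii) no other sample in the cohort carries a valid homozygous call for
  the same allele at that site — an allele observed in two lines is a
  shared pre-existing or systematic variant, not an independent per-line
  induced mutation.

The uniqueness universe for (iii) is the full set of regenerated call sets
supplied to the run (controls and treated together, across genotypes if
supplied together); calls that failed filtering do not veto, since they
assert nothing reliable. Optionally (`het_vetoes=True`, off by default
because het calls are discarded anyway) heterozygous carriers veto too.
If a sample's allele differs from both the reference and a non-reference
parental allele, the site is tri-allelic in the cohort context and is
excluded rather than called.

These rules guarantee that an accepted (chromosome, position, mutant allele)
triple appears in exactly one sample of a cohort run.

## Frequencies, spectrum, and background decomposition

Per-sample mutation frequency is `n / (callable_size / 1e6)` mutations/Mb,
where `callable_size` is the cumulative length of regions in which a
confident call was possible for that sample. Using the per-sample callable
genome rather than the full genome length makes the estimator insensitive
to coverage differences: mutations at uncallable positions are lost from the
numerator in the same proportion as bases are lost from the denominator.
Gene-region frequency restricts the numerator to mutations inside the
supplied gene intervals (BED, 0-based half-open, merged if overlapping) and
divides by the cumulative merged interval length.

Substitutions are grouped strand-symmetrically into six classes — two
transitions (A/T→G/C, G/C→A/T) and four transversions (A/T→C/G, A/T→T/A,
G/C→T/A, G/C→C/G) — and the G/C→A/T share of a sample's spectrum is
reported as its EMS-signature summary.

Treatment-group means are arithmetic means of per-sample ratios at full
precision. The EMS-induced rate is the treated-group mean minus the
control-group mean (the somaclonal background), clamped at zero with a
warning if negative. Group spectra are compared per class by the difference
of group means of per-sample class fractions, with significance from a
two-sided label-permutation test (10,000 permutations, seeded); with fewer
than two samples in a group the class is reported as untestable, effect
only. A permutation test is used because the groups are small (three lines
per treatment in the emulated design), making parametric assumptions
fragile.

## Production tallies

`population_summary` tabulates DH-line production per genotype × EMS dose:
lines produced, lines harvested (seed set), and percentages. Row
percentages display as integers with half-up rounding; genotype and overall
percentages display at two decimals. All other displayed ratios use
half-even rounding to two decimals; every chained computation uses full
double precision, and rounding is display-only.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
starting at the genotype-call level (read simulation, alignment and base
quality are deliberately out of scope):

* **Reference** — iid random bases at a configurable GC content over
  `n_chromosomes` near-equal chromosomes (`chr1..chrN`), with
  non-overlapping gene intervals covering ≈ `gene_fraction` of each
  chromosome (one gene per equal-width block at a random offset).
* **Truth mutations** — per sample, Poisson counts over the genome:
  somaclonal at `somaclonal_rate`/Mb for every regenerated sample, plus EMS
  at `ems_rate`/Mb for treated samples only; parent replicates receive none.
  Each mutation's class is drawn first (somaclonal from the configurable
  six-class spectrum; EMS as G/C→A/T with probability
  `ems_gc_to_at_fraction`, the remainder uniform over the other five
  classes), then a position with a compatible reference base is
  rejection-sampled from unused positions; class plus reference base
  determine the mutant base. Infeasible rates (expected mutations exceeding
  a tenth of the genome, or a class with an empty base pool) raise a
  simulation error rather than looping forever.
* **Call sets** — every truth mutation becomes a homozygous-alternate (1/1)
  record with an integer depth drawn from a negative binomial (mean
  `mean_depth`, shape `depth_dispersion`). Genotype calls use diploid
  notation (0/0, 0/1, 1/1) although DH material is haploid, because upstream
  callers emit diploid-style calls and the filters are phrased on them.
  Spurious records are added at `genotype_error_rate` per base at unused
  positions: heterozygous with probability 0.5 (removed by the het filter),
  otherwise homozygous-alternate with a random non-reference allele (removed
  by cohort uniqueness, or surviving as the false positives the recovery
  tests measure).
* **Callable size** — defined as the number of reference positions whose
  simulated depth falls in `[min_depth, max_depth]`. Since per-position
  depths are iid, this count is distributed Binomial(genome length,
  P(depth ∈ window)) with the window mass taken from the negative-binomial
  CDF, and is drawn directly from that binomial instead of materialising
  tens of millions of per-position depths; the two procedures are
  distributionally identical. Depths at emitted variant records remain
  explicit draws, so the depth filter acts on them individually.

Determinism: one seed drives three independently spawned generators
(reference, truth, call sets); identical configurations produce
byte-identical FASTA/BED/VCF/TSV outputs.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| `somaclonal_rate` | 1.84 /Mb | tissue-culture background of the emulated barley design |
| `ems_rate` | 0.35 /Mb | EMS increment at the emulated in-culture dose |
| `ems_gc_to_at_fraction` | 0.9 | strong canonical EMS transition bias |
| somaclonal spectrum | 25/30/10/10/15/10 % | mildly transition-biased, G/C→A/T well under 50% — tissue-culture variation carries no strong EMS signature |
| `genome_length` | 50 Mb | scaled-down stand-in for a multi-Gb cereal genome; large enough for ~100 mutations/sample, small enough to simulate in seconds |
| `gc_content` | 0.44 | barley-like |
| `mean_depth`, `depth_dispersion` | 8×, 3 | low-coverage resequencing with overdispersion |
| `genotype_error_rate` | 1e-7 /base | sparse residual false variant records after upstream calling |
| samples | 2 parents, 3 controls, 3 treated | the emulated replication structure |
| `gene_fraction` | 0.034 | genic share matching a large cereal genome (~120 Mb of genes per ~3.5 Gb callable) |

What the generator does **not** emulate: linked errors (mapping ambiguity
is position-correlated in real data, iid here), depth correlation along the
genome, reference bias, shared somaclonal hotspots, indels, and residual
heterozygosity in the starting material. Passing recovery tests therefore
demonstrate correctness of the calling logic and the statistical estimators
under the assumed error model, not robustness to structured artifacts in
real alignments.

## Parameter recovery and problem sizes

The recovery analysis simulates the study conditions above over 10
replicate cohorts of a 50 Mb genome (≈3,500 truth mutations in total per
run) and re-estimates the control mean, treated mean, induced rate, and
treated-cohort G/C→A/T fraction end-to-end through the filter → baseline →
call → frequency chain. Estimates agree with the generating parameters
within Monte-Carlo 3σ. Two small biases are understood and below that
resolution: homozygous false-positive error records inflate both group
means by ≈ +0.05/Mb at the default error rate (cancelling in the induced
rate), and truth mutations shared between samples by chance are suppressed
by the uniqueness criterion (a per-cohort handful at these rates).

The brute-force oracle used in testing re-implements criteria (i)–(iii)
site-major and is checked for exact agreement with the production caller on
100 randomized adversarial cohorts (10 kb genome, 2 parents, 5 samples,
het/missing/multi-allelic calls, depth extremes, parent conflicts).

## Degenerate inputs and edge rules

* Empty filtered call sets are legal everywhere; zero mutations give ratio
  0.00, an empty spectrum reports counts of zero and an undefined (missing)
  G/C→A/T fraction.
* Zero callable size refuses to compute a frequency (division by zero is an
  error, not a 0).
* `mean_depth = 0` yields empty callable regions and, downstream, empty
  filtered output.
* A tally row with zero DH lines reports a missing percentage.
* Depth-window boundaries are inclusive on both ends.
* The bundled production table's overall harvest percentage computes to
  70.61%; the package reports its computed value.
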