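"""Synthetic mutagenized-genome generator.

Emulates the statistical structure the analysis assumes, at the genotype-call
level (no reads): a random reference genome with annotated gene intervals; a
cohort of doubled-haploid samples — seed-germinated parent replicates,
regenerated controls (tissue-culture only) and regenerated treated samples
(tissue culture + EMS); per-sample truth mutations with a weakly biased
somaclonal spectrum and a strongly G/C→A/T-biased EMS component; and
per-sample VCF-style call sets with negative-binomial depths, depth-dependent
callability and sporadic genotype-call errors.

Two mutation processes per sample, both Poisson in count over the genome:

* somaclonal — tissue-culture variation, present in controls and treated
  samples alike, drawn from a configurable six-class spectrum;
* EMS — present only in treated samples; each mutation is a G→A or C→T
  transition with probability ``ems_gc_to_at_fraction`` (sited on a G/C
  base), otherwise one of the five remaining classes uniformly.

True mutations are emitted as homozygous-alternate (1/1) calls: DH material
is homozygous at every locus. Error sites are placed uniformly at random,
heterozygous with probability 0.5 (removed by the het filter) else
homozygous-alternate (removed by cohort uniqueness, or surviving as the
false positives recovery tests measure).

Coordinates: VCF positions are 1-based; BED gene intervals 0-based
half-open. Chromosomes are named ``chr1..chrN``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, IntegrityError, SimulationError
from .io import GeneIntervals, Genotype, GenotypeCall, Role, SampleCallSet, write_callable_sizes, write_vcf
from .spectrum import SubstitutionClass

__all__ = [
    "SimulationConfig",
    "ReferenceGenome",
    "TruthRecord",
    "TruthTable",
    "SimulationResult",
    "simulate_reference",
    "inject_mutations",
    "generate_callsets",
    "simulate",
    "write_simulation",
]

_BASE_CHARS = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = {"A": 0, "C": 1, "G": 2, "T": 3}
_GC_CODES = (1, 2)  # C, G

# (class, ref base) -> mutant base; each class pairs a substitution with its
# reverse-strand complement, so ref determines mutant uniquely.
_MUTANT_OF: dict[tuple[SubstitutionClass, str], str] = {
    (SubstitutionClass.GC_to_AT, "G"): "A",
    (SubstitutionClass.GC_to_AT, "C"): "T",
    (SubstitutionClass.AT_to_GC, "A"): "G",
    (SubstitutionClass.AT_to_GC, "T"): "C",
    (SubstitutionClass.AT_to_CG, "A"): "C",
    (SubstitutionClass.AT_to_CG, "T"): "G",
    (SubstitutionClass.AT_to_TA, "A"): "T",
    (SubstitutionClass.AT_to_TA, "T"): "A",
    (SubstitutionClass.GC_to_TA, "G"): "T",
    (SubstitutionClass.GC_to_TA, "C"): "A",
    (SubstitutionClass.GC_to_CG, "G"): "C",
    (SubstitutionClass.GC_to_CG, "C"): "G",
}

_GC_CLASSES = frozenset(
    {SubstitutionClass.GC_to_AT, SubstitutionClass.GC_to_TA, SubstitutionClass.GC_to_CG}
)

#: Default somaclonal spectrum: mildly transition-biased, with the G/C→A/T
#: share well under one half (tissue-culture variation carries no strong EMS
#: signature).
DEFAULT_SOMACLONAL_SPECTRUM: dict[SubstitutionClass, float] = {
    SubstitutionClass.AT_to_GC: 0.25,
    SubstitutionClass.GC_to_AT: 0.30,
    SubstitutionClass.AT_to_CG: 0.10,
    SubstitutionClass.AT_to_TA: 0.10,
    SubstitutionClass.GC_to_TA: 0.15,
    SubstitutionClass.GC_to_CG: 0.10,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults mirror the barley microspore-mutagenesis study conditions:
    ~1.84 somaclonal mutations/Mb, ~0.35 EMS-induced mutations/Mb on top for
    treated samples, a strongly G/C→A/T-biased EMS spectrum, 3 controls and
    3 treated samples at roughly 8× depth, with a genome scaled down to
    50 Mb so cohorts simulate in seconds.
    """

    genome_length: int = 50_000_000
    n_chromosomes: int = 5
    gc_content: float = 0.44  # barley-like
    somaclonal_rate: float = 1.84  # mutations per Mb per sample
    ems_rate: float = 0.35  # additional mutations per Mb in treated samples
    ems_gc_to_at_fraction: float = 0.9
    somaclonal_spectrum: Mapping[SubstitutionClass, float] = field(
        default_factory=lambda: dict(DEFAULT_SOMACLONAL_SPECTRUM)
    )
    mean_depth: float = 8.0
    depth_dispersion: float = 3.0  # negative-binomial shape; smaller = noisier
    genotype_error_rate: float = 1e-7  # spurious variant records per base
    n_control_samples: int = 3
    n_treated_samples: int = 3
    n_parent_replicates: int = 2
    gene_fraction: float = 0.034  # genic share of the genome
    min_depth: int = 2  # callable-window floor (matches the call filter)
    max_depth: int = 30  # callable-window cap
    rng_seed: int = 0

    def __post_init__(self) -> None:
        def bad(name, why):
            raise ConfigError(f"{name}: {why}")

        if self.genome_length < 1000:
            bad("genome_length", f"must be >= 1000, got {self.genome_length}")
        for name in ("n_chromosomes", "n_control_samples", "n_parent_replicates"):
            if getattr(self, name) < 1:
                bad(name, f"must be >= 1, got {getattr(self, name)}")
        if self.n_treated_samples < 0:
            bad("n_treated_samples", f"must be >= 0, got {self.n_treated_samples}")
        for name in ("gc_content", "ems_gc_to_at_fraction", "genotype_error_rate", "gene_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad(name, f"must be in [0, 1], got {v}")
        for name in ("somaclonal_rate", "ems_rate", "mean_depth"):
            if getattr(self, name) < 0:
                bad(name, f"must be >= 0, got {getattr(self, name)}")
        if self.depth_dispersion <= 0:
            bad("depth_dispersion", f"must be > 0, got {self.depth_dispersion}")
        if not (1 <= self.min_depth <= self.max_depth):
            bad("min_depth/max_depth", f"need 1 <= min <= max, got [{self.min_depth}, {self.max_depth}]")
        spec = dict(self.somaclonal_spectrum)
        if set(spec) != set(SubstitutionClass):
            bad("somaclonal_spectrum", "must provide a probability for all six classes")
        if any(v < 0 for v in spec.values()):
            bad("somaclonal_spectrum", "probabilities must be >= 0")
        if abs(sum(spec.values()) - 1.0) > 1e-9:
            bad("somaclonal_spectrum", f"must sum to 1, got {sum(spec.values())!r}")

    # -- flat key=value (de)serialization --------------------------------

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if f.name == "somaclonal_spectrum":
                    v = ",".join(f"{cls.name}:{p}" for cls, p in v.items())
                fh.write(f"{f.name}={v}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                kv[key.strip()] = val.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name not in kv:
                continue
            raw = kv[f.name]
            if f.name == "somaclonal_spectrum":
                spec = {}
                for item in raw.split(","):
                    name, _, p = item.partition(":")
                    spec[SubstitutionClass[name.strip()]] = float(p)
                kwargs[f.name] = spec
            elif f.type == "int" or isinstance(f.default, int):
                kwargs[f.name] = int(raw)
            else:
                kwargs[f.name] = float(raw)
        unknown = set(kv) - {f.name for f in fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class ReferenceGenome:
    """Simulated reference: base codes per chromosome plus gene intervals."""

    chromosomes: dict[str, np.ndarray]  # name -> uint8 codes (A=0,C=1,G=2,T=3)
    genes: list[tuple[str, int, int]]  # 0-based half-open

    @property
    def total_length(self) -> int:
        return sum(len(a) for a in self.chromosomes.values())

    @property
    def gc_fraction(self) -> float:
        gc = sum(int(np.isin(a, _GC_CODES).sum()) for a in self.chromosomes.values())
        return gc / self.total_length

    def base(self, chromosome: str, position: int) -> str:
        """Reference base at a 1-based position."""
        return chr(_BASE_CHARS[self.chromosomes[chromosome][position - 1]])

    def sequence(self, chromosome: str) -> str:
        return _BASE_CHARS[self.chromosomes[chromosome]].tobytes().decode()

    def gene_intervals(self) -> GeneIntervals:
        return GeneIntervals(self.genes)

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in self.chromosomes:
                fh.write(f">{name}\n")
                seq = self.sequence(name)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_genes_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.genes:
                fh.write(f"{chrom}\t{start}\t{end}\n")


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    chromosome: str
    position: int  # 1-based
    ref_base: str
    mutant_base: str
    origin: str  # "somaclonal" | "ems"

    def __post_init__(self) -> None:
        if self.ref_base == self.mutant_base:
            raise ValueError("truth record requires ref != mutant")
        if self.origin not in ("somaclonal", "ems"):
            raise ValueError(f"origin must be somaclonal|ems, got {self.origin}")


@dataclass
class TruthTable:
    """Ground-truth injected mutations, for recovery testing."""

    records: list[TruthRecord] = field(default_factory=list)

    def by_sample(self) -> dict[str, list[TruthRecord]]:
        out: dict[str, list[TruthRecord]] = {}
        for r in self.records:
            out.setdefault(r.sample_id, []).append(r)
        return out

    def validate_against(self, genome: ReferenceGenome) -> None:
        seen = set()
        for r in self.records:
            key = (r.sample_id, r.chromosome, r.position)
            if key in seen:
                raise IntegrityError(f"duplicate truth record {key}")
            seen.add(key)
            if genome.base(r.chromosome, r.position) != r.ref_base:
                raise IntegrityError(
                    f"truth ref {r.ref_base} at {r.chromosome}:{r.position} "
                    f"disagrees with reference {genome.base(r.chromosome, r.position)}"
                )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tchromosome\tposition\tref_base\tmutant_base\torigin\n")
            for r in sorted(self.records, key=lambda r: (r.sample_id, r.chromosome, r.position)):
                fh.write(
                    f"{r.sample_id}\t{r.chromosome}\t{r.position}\t{r.ref_base}"
                    f"\t{r.mutant_base}\t{r.origin}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                s, c, p, ref, mut, origin = line.rstrip("\n").split("\t")
                table.records.append(TruthRecord(s, c, int(p), ref, mut, origin))
        return table


def sample_names(config: SimulationConfig) -> dict[str, Role]:
    """Deterministic sample naming: parents, controls, treated."""
    names: dict[str, Role] = {}
    for i in range(1, config.n_parent_replicates + 1):
        names[f"parent_{i}"] = Role.PARENT_SEED
    for i in range(1, config.n_control_samples + 1):
        names[f"control_{i}"] = Role.REGENERATED_CONTROL
    for i in range(1, config.n_treated_samples + 1):
        names[f"treated_{i}"] = Role.REGENERATED_TREATED
    return names


def _chromosome_lengths(config: SimulationConfig) -> list[int]:
    base, rem = divmod(config.genome_length, config.n_chromosomes)
    return [base + (1 if i < rem else 0) for i in range(config.n_chromosomes)]


def simulate_reference(config: SimulationConfig, rng: np.random.Generator | None = None) -> ReferenceGenome:
    """Draw an iid random genome at the configured GC content, plus genes.

    Gene intervals are non-overlapping and cover ≈ ``gene_fraction`` of each
    chromosome: the chromosome is cut into equal blocks, one gene placed at a
    random offset inside each block.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chromosomes: dict[str, np.ndarray] = {}
    genes: list[tuple[str, int, int]] = []
    for i, length in enumerate(_chromosome_lengths(config), 1):
        name = f"chr{i}"
        chromosomes[name] = rng.choice(4, size=length, p=p).astype(np.uint8)
        target = config.gene_fraction * length
        mean_gene = 3000.0
        n_genes = int(round(target / mean_gene))
        if target > 0 and n_genes == 0 and target >= 1:
            n_genes = 1
        if n_genes > 0:
            block = length // n_genes
            g_len = max(1, min(block, int(round(target / n_genes))))
            for j in range(n_genes):
                lo = j * block
                start = lo + int(rng.integers(0, block - g_len + 1))
                genes.append((name, start, start + g_len))
    return ReferenceGenome(chromosomes=chromosomes, genes=genes)


def _draw_site(
    rng: np.random.Generator,
    genome: ReferenceGenome,
    chrom_names: list[str],
    chrom_probs: np.ndarray,
    need_gc: bool,
    used: set[tuple[str, int]],
    max_tries: int = 100_000,
) -> tuple[str, int, str]:
    """Rejection-sample an unused position whose ref base is in the needed pool."""
    for _ in range(max_tries):
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_probs))]
        pos = int(rng.integers(1, len(genome.chromosomes[chrom]) + 1))
        code = int(genome.chromosomes[chrom][pos - 1])
        if (code in _GC_CODES) != need_gc:
            continue
        if (chrom, pos) in used:
            continue
        return chrom, pos, chr(_BASE_CHARS[code])
    raise SimulationError(
        "could not place a mutation on an unused "
        f"{'G/C' if need_gc else 'A/T'} base after {max_tries} tries; "
        "rates likely exceed the eligible bases"
    )


def inject_mutations(
    genome: ReferenceGenome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Draw per-sample truth mutations.

    Treated samples receive Poisson(somaclonal_rate × Mb) somaclonal plus
    Poisson(ems_rate × Mb) EMS mutations; controls the somaclonal component
    only; parent replicates none. Positions are distinct within a sample.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    length = genome.total_length
    mb = length / 1e6
    expected = (config.somaclonal_rate + config.ems_rate) * mb
    if expected > 0.1 * length:
        raise SimulationError(
            f"expected {expected:.0f} mutations per sample on a {length} bp "
            "genome; rates imply more mutations than eligible bases"
        )
    gc_pool = sum(int(np.isin(a, _GC_CODES).sum()) for a in genome.chromosomes.values())
    at_pool = length - gc_pool

    chrom_names = list(genome.chromosomes)
    lens = np.array([len(genome.chromosomes[c]) for c in chrom_names], dtype=float)
    chrom_probs = lens / lens.sum()

    classes = list(SubstitutionClass)
    som_probs = np.array([config.somaclonal_spectrum[c] for c in classes])
    non_gc_at = [c for c in classes if c is not SubstitutionClass.GC_to_AT]

    table = TruthTable()
    for sample, role in sample_names(config).items():
        if role is Role.PARENT_SEED:
            continue
        n_som = int(rng.poisson(config.somaclonal_rate * mb))
        n_ems = (
            int(rng.poisson(config.ems_rate * mb))
            if role is Role.REGENERATED_TREATED
            else 0
        )
        used: set[tuple[str, int]] = set()
        draws: list[tuple[SubstitutionClass, str]] = []
        for _ in range(n_som):
            draws.append((classes[int(rng.choice(len(classes), p=som_probs))], "somaclonal"))
        for _ in range(n_ems):
            if rng.random() < config.ems_gc_to_at_fraction:
                cls = SubstitutionClass.GC_to_AT
            else:
                cls = non_gc_at[int(rng.integers(0, len(non_gc_at)))]
            draws.append((cls, "ems"))
        for cls, origin in draws:
            need_gc = cls in _GC_CLASSES
            if (gc_pool if need_gc else at_pool) == 0:
                raise SimulationError(
                    f"class {cls.label} needs a {'G/C' if need_gc else 'A/T'} base "
                    "but the genome has none"
                )
            chrom, pos, ref = _draw_site(rng, genome, chrom_names, chrom_probs, need_gc, used)
            used.add((chrom, pos))
            table.records.append(
                TruthRecord(
                    sample_id=sample,
                    chromosome=chrom,
                    position=pos,
                    ref_base=ref,
                    mutant_base=_MUTANT_OF[(cls, ref)],
                    origin=origin,
                )
            )
    return table


def _depth_window_mass(config: SimulationConfig) -> float:
    """P(depth in [min_depth, max_depth]) under the NB depth model."""
    if config.mean_depth == 0:
        return 1.0 if config.min_depth <= 0 else 0.0
    k = config.depth_dispersion
    p = k / (k + config.mean_depth)
    return float(
        stats.nbinom.cdf(config.max_depth, k, p) - stats.nbinom.cdf(config.min_depth - 1, k, p)
    )


def _draw_depths(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    if config.mean_depth == 0:
        return np.zeros(n, dtype=int)
    k = config.depth_dispersion
    p = k / (k + config.mean_depth)
    return rng.negative_binomial(k, p, size=n)


def generate_callsets(
    genome: ReferenceGenome,
    truth: TruthTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, SampleCallSet]:
    """Turn truth mutations into per-sample call sets with noise.

    Per sample: every truth mutation becomes a 1/1 record with a
    negative-binomial depth; Poisson(genotype_error_rate × genome) spurious
    records are added at unused positions (0/1 with probability 0.5, else
    1/1 with a random non-reference allele); the callable-region size is the
    number of genome positions whose depth would fall in the accepted window,
    drawn as Binomial(genome_length, P(depth in window)).
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    truth.validate_against(genome)
    length = genome.total_length
    p_window = _depth_window_mass(config)
    chrom_names = list(genome.chromosomes)
    lens = np.array([len(genome.chromosomes[c]) for c in chrom_names], dtype=float)
    chrom_probs = lens / lens.sum()

    by_sample = truth.by_sample()
    callsets: dict[str, SampleCallSet] = {}
    for sample, role in sample_names(config).items():
        recs = sorted(by_sample.get(sample, []), key=lambda r: (r.chromosome, r.position))
        depths = _draw_depths(rng, config, len(recs))
        calls: dict[tuple[str, int], GenotypeCall] = {}
        for r, depth in zip(recs, depths):
            calls[(r.chromosome, r.position)] = GenotypeCall(
                chromosome=r.chromosome,
                position=r.position,
                ref_allele=r.ref_base,
                alt_alleles=(r.mutant_base,),
                genotype=Genotype.HOM_ALT,
                depth=int(depth),
            )
        n_err = int(rng.poisson(config.genotype_error_rate * length))
        err_depths = _draw_depths(rng, config, n_err)
        for depth in err_depths:
            while True:
                chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_probs))]
                pos = int(rng.integers(1, len(genome.chromosomes[chrom]) + 1))
                if (chrom, pos) not in calls:
                    break
            ref = genome.base(chrom, pos)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            gt = Genotype.HET if rng.random() < 0.5 else Genotype.HOM_ALT
            calls[(chrom, pos)] = GenotypeCall(
                chromosome=chrom,
                position=pos,
                ref_allele=ref,
                alt_alleles=(str(alt),),
                genotype=gt,
                depth=int(depth),
            )
        callable_size = int(rng.binomial(length, p_window))
        callsets[sample] = SampleCallSet(
            sample_id=sample, calls=calls, callable_size=callable_size, role=role
        )
    return callsets


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: ReferenceGenome
    truth: TruthTable
    callsets: dict[str, SampleCallSet]

    @property
    def callable_sizes(self) -> dict[str, int]:
        return {s: cs.callable_size for s, cs in self.callsets.items()}


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run reference → truth → call sets with independent child seeds."""
    seeds = np.random.SeedSequence(config.rng_seed).spawn(3)
    genome = simulate_reference(config, np.random.default_rng(seeds[0]))
    truth = inject_mutations(genome, config, np.random.default_rng(seeds[1]))
    callsets = generate_callsets(genome, truth, config, np.random.default_rng(seeds[2]))
    return SimulationResult(config=config, genome=genome, truth=truth, callsets=callsets)


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA / BED / per-sample VCFs / truth TSV / callable TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["reference"] = outdir / "reference.fa"
    result.genome.write_fasta(paths["reference"])
    paths["genes"] = outdir / "genes.bed"
    result.genome.write_genes_bed(paths["genes"])
    paths["truth"] = outdir / "truth.tsv"
    result.truth.write_tsv(paths["truth"])
    paths["callable"] = outdir / "callable_sizes.tsv"
    write_callable_sizes(result.callable_sizes, paths["callable"])
    contigs = {name: len(arr) for name, arr in result.genome.chromosomes.items()}
    for sample in sorted(result.callsets):
        p = outdir / f"{sample}.vcf"
        write_vcf(result.callsets[sample], p, contigs=contigs)
        paths[f"vcf:{sample}"] = p
    paths["config"] = outdir / "sim_config.txt"
    result.config.to_file(paths["config"])
    return paths
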