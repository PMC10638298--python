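"""Reading and writing the formats the pipeline touches.

The internal data model is deliberately small: a :class:`GenotypeCall` per
sample per site, gathered into a :class:`SampleCallSet` keyed by genomic
position. Only SNV records enter the model — indels and symbolic alleles are
dropped at read time with a logged count, since the analysis concerns
single-nucleotide mutations only.

Conventions: VCF positions are 1-based; BED intervals are 0-based half-open.
Genotypes use diploid notation (0/0, 0/1, 1/1) even though doubled-haploid
material is genetically homozygous, because upstream callers emit diploid
calls and the filtering rules are phrased on them. A record with missing GT
becomes ``Genotype.MISSING``; a missing DP is treated as depth 0, which a
depth-window filter then removes (conservative: no call confidence, no call).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from cyvcf2 import VCF
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .errors import VcfParseError

logger = logging.getLogger(__name__)

__all__ = [
    "Genotype",
    "Role",
    "GenotypeCall",
    "SampleCallSet",
    "GeneIntervals",
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "read_gene_intervals",
    "read_callable_sizes",
    "write_callable_sizes",
]

_BASES = frozenset("ACGT")


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Role(enum.Enum):
    """What a sequenced sample is, in the experimental design."""

    PARENT_SEED = "parent_seed"  # seed-germinated, untreated: baseline
    REGENERATED_CONTROL = "regenerated_control"  # microspore culture, no EMS
    REGENERATED_TREATED = "regenerated_treated"  # microspore culture + EMS


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype call at one site."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotype: Genotype
    depth: int
    called_alt_index: int = 0  # which alt the genotype refers to (multi-alt VCFs)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref_allele:
            raise ValueError("ref_allele must be non-empty")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.genotype is Genotype.HOM_ALT and not self.alt_alleles:
            raise ValueError("hom_alt call requires at least one alt allele")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chromosome, self.position)

    @property
    def called_allele(self) -> str | None:
        """The allele a homozygous call asserts; None for het/missing."""
        if self.genotype is Genotype.HOM_REF:
            return self.ref_allele
        if self.genotype is Genotype.HOM_ALT:
            return self.alt_alleles[self.called_alt_index]
        return None

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and self.ref_allele in _BASES and all(
            len(a) == 1 and a in _BASES for a in self.alt_alleles
        )


@dataclass
class SampleCallSet:
    """All calls of one sample plus its callable-region size in bases."""

    sample_id: str
    calls: dict[tuple[str, int], GenotypeCall] = field(default_factory=dict)
    callable_size: int = 0  # bases; 0 = unknown (frequency computation will refuse)
    role: Role = Role.REGENERATED_TREATED

    def __post_init__(self) -> None:
        if self.callable_size < 0:
            raise ValueError(f"callable_size must be >= 0, got {self.callable_size}")
        for key, call in self.calls.items():
            if key != call.key:
                raise ValueError(f"call set key {key} disagrees with call at {call.key}")

    def add(self, call: GenotypeCall) -> None:
        self.calls[call.key] = call

    def __len__(self) -> int:
        return len(self.calls)


class GeneIntervals:
    """Merged gene-coding intervals with 1-based membership queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"interval end must exceed start: {chrom}:{start}-{end}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)  # touching intervals merge too
        self.size = sum(iv.end - iv.begin for tree in self._trees.values() for iv in tree)

    def contains(self, chromosome: str, position: int) -> bool:
        """Membership of a 1-based position (BED intervals are 0-based)."""
        tree = self._trees.get(chromosome)
        return bool(tree is not None and tree.overlaps(position - 1))

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def read_gene_intervals(path: str | Path) -> GeneIntervals:
    """Read a BED3 file of gene-coding intervals (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
            intervals.append((chrom, start, end))
    gi = GeneIntervals(intervals)
    logger.info("read %d gene intervals (%d bp merged) from %s", len(intervals), gi.size, path)
    return gi


def _genotype_from_pair(a: int, b: int) -> tuple[Genotype, int]:
    """Classify an allele-index pair; returns (genotype, called_alt_index)."""
    if a < 0 or b < 0:
        return Genotype.MISSING, 0
    if a == b == 0:
        return Genotype.HOM_REF, 0
    if a == b:
        return Genotype.HOM_ALT, a - 1
    return Genotype.HET, 0


def read_vcf(
    path: str | Path,
    sample_id: str | None = None,
    role: Role = Role.REGENERATED_TREATED,
    callable_size: int = 0,
) -> SampleCallSet:
    """Read one sample's calls from a VCF (v4.2, GT and DP per sample).

    Multi-sample files are accepted with ``sample_id`` as selector; for a
    single-sample file the selector defaults to that sample. ``callable_size``
    comes from a sidecar table (see :func:`read_callable_sizes`) or, for
    synthetic data, from the simulator. Non-SNV records (indels, symbolic
    alleles) are dropped with a logged count.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"{path}: no sample columns")
    if sample_id is None:
        if len(samples) > 1:
            raise VcfParseError(f"{path}: multi-sample file requires a sample selector")
        sample_id = samples[0]
    try:
        idx = samples.index(sample_id)
    except ValueError:
        raise KeyError(f"sample {sample_id!r} not in {path} (has {samples})") from None

    callset = SampleCallSet(sample_id=sample_id, callable_size=callable_size, role=role)
    n_dropped = 0
    for rec_no, variant in enumerate(vcf, 1):
        try:
            ref = variant.REF
            alts = tuple(variant.ALT)
            if len(ref) != 1 or ref not in _BASES or any(
                len(a) != 1 or a not in _BASES for a in alts
            ):
                n_dropped += 1
                continue
            a, b = variant.genotypes[idx][0], variant.genotypes[idx][1]
            genotype, alt_idx = _genotype_from_pair(int(a), int(b))
            dp = variant.format("DP")
            depth = 0 if dp is None else max(0, int(dp[idx][0]))
            callset.add(
                GenotypeCall(
                    chromosome=variant.CHROM,
                    position=variant.POS,
                    ref_allele=ref,
                    alt_alleles=alts,
                    genotype=genotype,
                    depth=depth,
                    called_alt_index=alt_idx,
                )
            )
        except (VcfParseError, KeyError):
            raise
        except Exception as exc:  # malformed record content
            raise VcfParseError(f"{path}: record {rec_no}: {exc}") from exc
    vcf.close()
    if n_dropped:
        logger.info("%s: dropped %d non-SNV records", path, n_dropped)
    logger.info("%s: read %d SNV calls for sample %s", path, len(callset), sample_id)
    return callset


_GT_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_vcf(callset: SampleCallSet, path: str | Path, contigs: Mapping[str, int] | None = None) -> None:
    """Write a single-sample VCF v4.2 with GT and DP.

    ``contigs`` maps chromosome name to length for header lines; when absent,
    contig headers are derived from the calls without lengths.
    """
    keys = sorted(callset.calls, key=lambda k: (k[0], k[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dhmut\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in sorted({k[0] for k in keys}):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{callset.sample_id}\n")
        for key in keys:
            call = callset.calls[key]
            # hom-alt on a later alt needs the index rewritten
            gt = _GT_STRING[call.genotype]
            if call.genotype is Genotype.HOM_ALT and call.called_alt_index > 0:
                i = call.called_alt_index + 1
                gt = f"{i}/{i}"
            alt = ",".join(call.alt_alleles) if call.alt_alleles else "."
            fh.write(
                f"{call.chromosome}\t{call.position}\t.\t{call.ref_allele}\t{alt}"
                f"\t.\t.\t.\tGT:DP\t{gt}:{call.depth}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a reference FASTA into {chromosome: uppercase sequence}."""
    with Fasta(str(path), rebuild=False) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def read_callable_sizes(path: str | Path) -> dict[str, int]:
    """Read the sidecar TSV mapping sample_id -> callable size in bases."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("sample"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>size'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_callable_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcallable_size\n")
        for sample in sorted(sizes):
            fh.write(f"{sample}\t{sizes[sample]}\n")
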