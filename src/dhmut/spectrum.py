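"""Mutation frequencies, six-class substitution spectrum, and group comparison.

Single-nucleotide substitutions are grouped strand-symmetrically into six
classes: two transitions (A/T→G/C, G/C→A/T) and four transversions (A/T→C/G,
A/T→T/A, G/C→T/A, G/C→C/G). The G/C→A/T transition is the signature of EMS
(ethyl methanesulfonate) alkylation, so its share of a sample's spectrum is
reported as a normalized summary (``gc_to_at_fraction``).

Per-sample mutation frequency is the number of accepted homozygous SNVs
divided by the sample's callable genome size in Mb — the cumulative length of
regions where a confident genotype call was possible — and likewise for the
gene-coding region restricted to annotated intervals.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rounding import round2

__all__ = [
    "SubstitutionClass",
    "classify_substitution",
    "FrequencyReport",
    "SpectrumReport",
    "per_mb",
    "compute_frequency",
    "mean_frequency",
    "subtract_background",
    "spectrum_summary",
    "compare_spectra",
    "plot_spectrum",
]


class SubstitutionClass(enum.Enum):
    """The six strand-symmetric single-nucleotide substitution classes."""

    AT_to_GC = "A/T->G/C"  # transition
    GC_to_AT = "G/C->A/T"  # transition, EMS signature
    AT_to_CG = "A/T->C/G"  # transversion
    AT_to_TA = "A/T->T/A"  # transversion
    GC_to_TA = "G/C->T/A"  # transversion
    GC_to_CG = "G/C->C/G"  # transversion

    @property
    def label(self) -> str:
        return self.value

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Ordered (ref, mut) -> class; each class collects a substitution and its
# reverse-strand complement.
_CLASS_OF: dict[tuple[str, str], SubstitutionClass] = {
    ("A", "G"): SubstitutionClass.AT_to_GC,
    ("T", "C"): SubstitutionClass.AT_to_GC,
    ("G", "A"): SubstitutionClass.GC_to_AT,
    ("C", "T"): SubstitutionClass.GC_to_AT,
    ("A", "C"): SubstitutionClass.AT_to_CG,
    ("T", "G"): SubstitutionClass.AT_to_CG,
    ("A", "T"): SubstitutionClass.AT_to_TA,
    ("T", "A"): SubstitutionClass.AT_to_TA,
    ("G", "T"): SubstitutionClass.GC_to_TA,
    ("C", "A"): SubstitutionClass.GC_to_TA,
    ("G", "C"): SubstitutionClass.GC_to_CG,
    ("C", "G"): SubstitutionClass.GC_to_CG,
}


def classify_substitution(ref_base: str, mut_base: str) -> SubstitutionClass:
    """Map an ordered base substitution onto its strand-symmetric class.

    Parameters
    ----------
    ref_base, mut_base:
        Distinct single bases in ``{A, C, G, T}`` (case-insensitive).
    """
    r, m = str(ref_base).upper(), str(mut_base).upper()
    if r == m:
        raise ValueError(f"substitution requires distinct bases, got {r}->{m}")
    try:
        return _CLASS_OF[(r, m)]
    except KeyError:
        raise ValueError(f"bases must be in A/C/G/T, got {ref_base!r}->{mut_base!r}") from None


@dataclass(frozen=True)
class FrequencyReport:
    """Per-sample mutation counts and per-Mb ratios, genome-wide and genic."""

    sample_id: str
    n_mutations_genome: int
    callable_size: int  # bases
    ratio_genome: float  # mutations per Mb, full precision
    n_mutations_gene: int | None = None
    gene_region_size: int | None = None
    ratio_gene: float | None = None

    @property
    def ratio_genome_display(self) -> float:
        return round2(self.ratio_genome)

    @property
    def ratio_gene_display(self) -> float | None:
        return None if self.ratio_gene is None else round2(self.ratio_gene)


@dataclass(frozen=True)
class SpectrumReport:
    """Counts per substitution class for one sample (or pooled set)."""

    sample_id: str
    counts: Mapping[SubstitutionClass, int]
    total: int
    gc_to_at_fraction: float | None  # None when total == 0

    def fraction(self, cls: SubstitutionClass) -> float | None:
        if self.total == 0:
            return None
        return self.counts[cls] / self.total


def per_mb(n_mutations: int, size_bases: float) -> float:
    """Mutations per megabase: ``n / (size / 1e6)``. Full precision."""
    if size_bases <= 0:
        raise ValueError(f"size must be positive, got {size_bases}")
    if n_mutations < 0:
        raise ValueError(f"negative mutation count: {n_mutations}")
    return n_mutations / (size_bases / 1e6)


def compute_frequency(
    mutations: Sequence,
    callable_size: int,
    gene_intervals=None,
    sample_id: str = "",
) -> FrequencyReport:
    """Build a :class:`FrequencyReport` from accepted mutation records.

    ``mutations`` are records with ``in_gene_region`` flags (gene counts use
    only flagged records); ``gene_intervals``, when given, supplies the
    gene-region size denominator via its ``size`` attribute.
    """
    n = len(mutations)
    ratio = per_mb(n, callable_size)
    n_gene = gene_size = ratio_gene = None
    if gene_intervals is not None:
        gene_size = int(getattr(gene_intervals, "size", gene_intervals))
        n_gene = sum(1 for m in mutations if m.in_gene_region)
        ratio_gene = per_mb(n_gene, gene_size)
        if n_gene > n:  # pragma: no cover - defensive
            raise ValueError("gene-region count exceeds genome-wide count")
    return FrequencyReport(
        sample_id=sample_id,
        n_mutations_genome=n,
        callable_size=int(callable_size),
        ratio_genome=ratio,
        n_mutations_gene=n_gene,
        gene_region_size=gene_size,
        ratio_gene=ratio_gene,
    )


def mean_frequency(reports: Sequence) -> float:
    """Arithmetic mean of per-sample per-Mb ratios, at full precision.

    Accepts :class:`FrequencyReport` objects or bare ratios.
    """
    if len(reports) == 0:
        raise ValueError("mean_frequency requires at least one report")
    vals = [r.ratio_genome if isinstance(r, FrequencyReport) else float(r) for r in reports]
    return float(np.mean(vals))


def subtract_background(treated_mean: float, control_mean: float) -> float:
    """Induced mutation rate: treated minus tissue-culture background.

    Both inputs are per-Mb means; a negative difference (treated below
    control) is clamped to 0 with a warning, since a negative induced rate is
    not meaningful.
    """
    if treated_mean < 0 or control_mean < 0:
        raise ValueError("means must be non-negative")
    diff = treated_mean - control_mean
    if diff < 0:
        warnings.warn(
            f"treated mean {treated_mean:.4f} below control mean "
            f"{control_mean:.4f}; induced rate clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return diff


def spectrum_summary(mutations: Sequence, sample_id: str = "") -> SpectrumReport:
    """Tally substitution classes over accepted mutation records."""
    counts = {cls: 0 for cls in SubstitutionClass}
    for m in mutations:
        counts[m.substitution_class] += 1
    total = sum(counts.values())
    frac = counts[SubstitutionClass.GC_to_AT] / total if total else None
    return SpectrumReport(sample_id=sample_id, counts=counts, total=total, gc_to_at_fraction=frac)


def compare_spectra(
    group_a: Sequence[SpectrumReport],
    group_b: Sequence[SpectrumReport],
    n_permutations: int = 10_000,
    seed: int = 0,
    use_fractions: bool = True,
) -> pd.DataFrame:
    """Per-class effect (group_b − group_a) with a permutation test.

    For each class the statistic is the difference of group means of
    per-sample class fractions (or raw counts with ``use_fractions=False``).
    Significance comes from a label-permutation null (two-sided, seeded);
    with fewer than two samples in either group the class is reported as
    untestable and only the effect is given.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    testable = len(group_a) >= 2 and len(group_b) >= 2
    rng = np.random.default_rng(seed)
    rows = []
    n_a = len(group_a)
    for cls in SubstitutionClass:
        def val(rep: SpectrumReport) -> float:
            if use_fractions:
                f = rep.fraction(cls)
                return 0.0 if f is None else f
            return float(rep.counts[cls])

        a = np.array([val(r) for r in group_a])
        b = np.array([val(r) for r in group_b])
        effect = float(b.mean() - a.mean())
        p = None
        if testable:
            pooled = np.concatenate([a, b])
            null = np.empty(n_permutations)
            for i in range(n_permutations):
                perm = rng.permutation(pooled)
                null[i] = perm[n_a:].mean() - perm[:n_a].mean()
            # permutation p-value with the observed statistic included
            p = float((np.sum(np.abs(null) >= abs(effect) - 1e-12) + 1) / (n_permutations + 1))
        rows.append(
            {
                "class": cls.label,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "effect": effect,
                "p_value": p,
                "testable": testable,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def plot_spectrum(reports: Sequence[SpectrumReport], path: str) -> None:
    """Grouped per-class count bars, one group of bars per sample."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = list(SubstitutionClass)
    x = np.arange(len(classes))
    width = 0.8 / max(len(reports), 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    for i, rep in enumerate(reports):
        ax.bar(
            x + i * width,
            [rep.counts[c] for c in classes],
            width,
            label=rep.sample_id or f"sample {i + 1}",
        )
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels([c.label for c in classes], rotation=30, ha="right")
    ax.set_ylabel("mutations")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
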