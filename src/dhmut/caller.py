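"""Induced-mutation identification against a parental baseline.

A mutation is accepted in a regenerated sample when three criteria hold at
the site:

(i)   the parental state is homozygous — established from seed-germinated
      plants of the same genotype, or assumed homozygous-reference where the
      parents are silent (they were called against the same reference);
(ii)  the sample's call is homozygous and its allele differs from the
      parental allele;
(iii) cohort uniqueness — no other sequenced sample in the run carries a
      valid homozygous call for the same allele at that site. Shared alleles
      are pre-existing or systematic variants, not per-line induced
      mutations.

Sites where parental replicates give conflicting valid calls are flagged
unresolvable and excluded from calling in every sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError
from .filters import FilterConfig, filter_calls
from .io import GeneIntervals, Genotype, SampleCallSet
from .spectrum import SubstitutionClass, classify_substitution

logger = logging.getLogger(__name__)

__all__ = ["BaselineSite", "ParentalBaseline", "MutationRecord", "build_baseline", "identify_mutations", "call_cohort"]

Site = tuple[str, int]


@dataclass(frozen=True)
class BaselineSite:
    """Consensus parental state at one site: a homozygous allele."""

    allele: str
    is_alt: bool
    ref_allele: str
    support: int  # parent replicates agreeing

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("baseline site needs support >= 1")


@dataclass
class ParentalBaseline:
    """Sites where the parent genotype is established, plus conflicts."""

    genotype_name: str
    sites: dict[Site, BaselineSite] = field(default_factory=dict)
    unresolvable: set[Site] = field(default_factory=set)


@dataclass(frozen=True)
class MutationRecord:
    """An accepted induced homozygous mutation in one sample."""

    sample_id: str
    chromosome: str
    position: int  # 1-based
    parental_base: str
    mutant_base: str
    substitution_class: SubstitutionClass
    in_gene_region: bool = False

    def __post_init__(self) -> None:
        if self.parental_base == self.mutant_base:
            raise ValueError("mutation requires parental_base != mutant_base")

    @property
    def site(self) -> Site:
        return (self.chromosome, self.position)


def build_baseline(
    parent_callsets: Sequence[SampleCallSet],
    cfg: FilterConfig | None = None,
    genotype_name: str = "",
    prefiltered: bool = False,
) -> ParentalBaseline:
    """Derive the parental baseline from seed-germinated replicates.

    Each replicate is filtered (unless ``prefiltered``), then a site enters
    the baseline with the allele on which every replicate holding a valid
    homozygous call agrees; conflicting valid calls mark the site
    unresolvable, excluding it from mutation calling everywhere.
    """
    if not parent_callsets:
        raise ConfigError("build_baseline requires at least one parent call set")
    filtered = (
        list(parent_callsets)
        if prefiltered
        else [filter_calls(cs, cfg)[0] for cs in parent_callsets]
    )
    baseline = ParentalBaseline(genotype_name=genotype_name or filtered[0].sample_id)
    votes: dict[Site, list] = {}
    for cs in filtered:
        for site, call in cs.calls.items():
            allele = call.called_allele
            if allele is None:  # het/missing survive only with permissive cfg
                continue
            votes.setdefault(site, []).append(call)
    for site, calls in votes.items():
        alleles = {c.called_allele for c in calls}
        if len(alleles) == 1:
            call = calls[0]
            baseline.sites[site] = BaselineSite(
                allele=call.called_allele,
                is_alt=call.genotype is Genotype.HOM_ALT,
                ref_allele=call.ref_allele,
                support=len(calls),
            )
        else:
            baseline.unresolvable.add(site)
    if baseline.unresolvable:
        logger.info(
            "baseline %s: %d sites unresolvable (conflicting parent calls)",
            baseline.genotype_name,
            len(baseline.unresolvable),
        )
    return baseline


def _carries_allele(callset: SampleCallSet, site: Site, allele: str, het_vetoes: bool) -> bool:
    """Does this sample hold a valid call asserting ``allele`` at ``site``?"""
    call = callset.calls.get(site)
    if call is None:
        return False
    if call.called_allele == allele:
        return True
    if het_vetoes and call.genotype is Genotype.HET:
        return allele == call.ref_allele or allele in call.alt_alleles
    return False


def identify_mutations(
    sample: SampleCallSet,
    baseline: ParentalBaseline,
    cohort: Sequence[SampleCallSet],
    gene_intervals: GeneIntervals | None = None,
    require_parent_call: bool = False,
    het_vetoes: bool = False,
) -> list[MutationRecord]:
    """Accept induced mutations for one sample under criteria (i)–(iii).

    ``cohort`` is the full set of filtered, sequenced call sets in the run
    (the sample itself included); it defines the uniqueness universe for
    criterion (iii). Where the baseline is silent at a site, the parental
    state defaults to homozygous-reference unless ``require_parent_call``.
    """
    if not any(cs is sample or cs.sample_id == sample.sample_id for cs in cohort):
        raise ConfigError(f"sample {sample.sample_id!r} not among the cohort call sets")
    others = [cs for cs in cohort if cs.sample_id != sample.sample_id]

    records = []
    for site, call in sample.calls.items():
        if site in baseline.unresolvable:
            continue
        allele = call.called_allele
        if allele is None or not call.is_snv:
            continue  # het/missing or non-SNV: cannot assert a homozygous SNV
        base_site = baseline.sites.get(site)
        if base_site is None:
            if require_parent_call:
                continue
            parental = call.ref_allele  # reference stands in for the silent parent
        else:
            parental = base_site.allele
            # tri-allelic in cohort context: sample allele differs from both
            # the reference and a non-reference parental allele
            if (
                base_site.is_alt
                and allele != parental
                and allele != call.ref_allele
            ):
                continue
        if allele == parental:
            continue
        if any(_carries_allele(cs, site, allele, het_vetoes) for cs in others):
            continue  # criterion (iii): allele seen in another sample
        records.append(
            MutationRecord(
                sample_id=sample.sample_id,
                chromosome=site[0],
                position=site[1],
                parental_base=parental,
                mutant_base=allele,
                substitution_class=classify_substitution(parental, allele),
                in_gene_region=(
                    gene_intervals.contains(site[0], site[1]) if gene_intervals else False
                ),
            )
        )
    records.sort(key=lambda r: (r.chromosome, r.position))
    return records


def call_cohort(
    samples: Sequence[SampleCallSet],
    baseline: ParentalBaseline,
    cohort: Sequence[SampleCallSet] | None = None,
    gene_intervals: GeneIntervals | None = None,
    **kwargs,
) -> dict[str, list[MutationRecord]]:
    """Run :func:`identify_mutations` for each sample against one cohort.

    ``cohort`` defaults to ``samples`` (uniqueness scoped to the run); pass a
    larger list to scope uniqueness across genotypes sequenced together.
    """
    cohort = list(cohort) if cohort is not None else list(samples)
    return {
        cs.sample_id: identify_mutations(cs, baseline, cohort, gene_intervals, **kwargs)
        for cs in samples
    }
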