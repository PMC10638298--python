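"""Shared fixtures and the independent brute-force caller oracle."""

from __future__ import annotations

import numpy as np
import pytest

from dhmut.io import Genotype, GenotypeCall, Role, SampleCallSet


def mk_call(
    chrom="chr1",
    pos=100,
    ref="G",
    alts=("A",),
    gt=Genotype.HOM_ALT,
    depth=12,
):
    return GenotypeCall(
        chromosome=chrom,
        position=pos,
        ref_allele=ref,
        alt_alleles=tuple(alts),
        genotype=gt,
        depth=depth,
    )


def mk_callset(sample_id, calls, role=Role.REGENERATED_TREATED, callable_size=1_000_000):
    return SampleCallSet(
        sample_id=sample_id,
        calls={c.key: c for c in calls},
        callable_size=callable_size,
        role=role,
    )


def brute_force_identify(parents, samples, require_parent_call=False, het_vetoes=False):
    """Exhaustive per-site reimplementation of the acceptance criteria.

    Site-major, straight off the three rules: (i) parental state homozygous
    (consensus of valid parent calls, reference default where silent),
    (ii) sample call homozygous with a differing allele, (iii) allele absent
    from every other sample's valid calls at that site. Inputs are filtered
    call sets. Returns {sample_id: set((chrom, pos, parental, mutant))}.
    """
    sites = sorted({s for cs in samples for s in cs.calls} | {s for cs in parents for s in cs.calls})
    out = {cs.sample_id: set() for cs in samples}
    for site in sites:
        parent_calls = [
            cs.calls[site]
            for cs in parents
            if site in cs.calls and cs.calls[site].called_allele is not None
        ]
        parent_alleles = {c.called_allele for c in parent_calls}
        if len(parent_alleles) > 1:
            continue  # unresolvable: conflicting parent replicates
        if parent_alleles:
            parental_allele = next(iter(parent_alleles))
            parental_is_alt = parent_calls[0].genotype is Genotype.HOM_ALT
        else:
            parental_allele = None
            parental_is_alt = False
        for cs in samples:
            call = cs.calls.get(site)
            if call is None or call.called_allele is None or not call.is_snv:
                continue
            allele = call.called_allele
            if parental_allele is None:
                if require_parent_call:
                    continue
                parental = call.ref_allele
            else:
                parental = parental_allele
                if parental_is_alt and allele not in (parental, call.ref_allele):
                    continue  # tri-allelic in cohort context
            if allele == parental:
                continue
            vetoed = False
            for other in samples:
                if other.sample_id == cs.sample_id:
                    continue
                oc = other.calls.get(site)
                if oc is None:
                    continue
                if oc.called_allele == allele:
                    vetoed = True
                elif het_vetoes and oc.genotype is Genotype.HET and (
                    allele == oc.ref_allele or allele in oc.alt_alleles
                ):
                    vetoed = True
                if vetoed:
                    break
            if not vetoed:
                out[cs.sample_id].add((site[0], site[1], parental, allele))
    return out


def random_cohort(rng: np.random.Generator, n_parents=2, n_samples=5, n_sites=40, genome_len=10_000):
    """An adversarial random cohort over a toy genome: het/missing calls,
    shared alleles, multi-allelic records, parent conflicts, depth extremes."""
    bases = "ACGT"
    positions = sorted(rng.choice(genome_len, size=n_sites, replace=False) + 1)
    refs = {int(p): bases[rng.integers(4)] for p in positions}

    def random_callset(sample_id, role):
        calls = []
        for p in positions:
            if rng.random() > 0.6:
                continue
            ref = refs[int(p)]
            n_alts = 1 if rng.random() < 0.85 else 2
            alts = list(rng.choice([b for b in bases if b != ref], size=n_alts, replace=False))
            gt = rng.choice(
                [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING],
                p=[0.3, 0.2, 0.45, 0.05],
            )
            depth = int(rng.integers(0, 41))
            calls.append(mk_call("chr1", int(p), ref, tuple(alts), gt, depth))
        return mk_callset(sample_id, calls, role=role, callable_size=genome_len)

    parents = [random_callset(f"parent_{i}", Role.PARENT_SEED) for i in range(1, n_parents + 1)]
    samples = [
        random_callset(f"sample_{i}", Role.REGENERATED_TREATED) for i in range(1, n_samples + 1)
    ]
    return parents, samples


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
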