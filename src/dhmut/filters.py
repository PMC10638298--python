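"""Site-level filtration of genotype calls before mutation identification.

Three rules, applied per sample per site: (1) only bi-allelic variants are
accepted; (2) a call is valid only when its read depth lies in an inclusive
window (default 2–30 reads — the floor removes single-read artifacts, the cap
removes collapsed-repeat pileups); (3) heterozygous calls are discarded,
since doubled-haploid material is homozygous at every locus and a het call
indicates a mapping or calling artifact.

Homozygous-reference calls are retained here: they are needed later to
establish the parental state at a site. Drop precedence is fixed
(multi-allelic → depth → heterozygous/missing) so each call is counted under
exactly one reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .io import Genotype, SampleCallSet

__all__ = ["FilterConfig", "FilterStats", "filter_calls"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for site-level call validity."""

    min_depth: int = 2
    max_depth: int = 30
    require_biallelic: bool = True
    drop_heterozygous: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_depth <= self.max_depth):
            raise ValueError(
                f"need 1 <= min_depth <= max_depth, got [{self.min_depth}, {self.max_depth}]"
            )


@dataclass
class FilterStats:
    """Per-reason drop counts; drops plus retained always sum to the input."""

    n_input: int = 0
    n_multiallelic: int = 0
    n_depth: int = 0
    n_heterozygous: int = 0
    n_missing: int = 0
    n_retained: int = 0

    @property
    def consistent(self) -> bool:
        return (
            self.n_multiallelic + self.n_depth + self.n_heterozygous + self.n_missing
            + self.n_retained
            == self.n_input
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "multiallelic": self.n_multiallelic,
            "depth": self.n_depth,
            "heterozygous": self.n_heterozygous,
            "missing": self.n_missing,
            "retained": self.n_retained,
        }


def filter_calls(callset: SampleCallSet, cfg: FilterConfig | None = None) -> tuple[SampleCallSet, FilterStats]:
    """Apply the filtration rules to one sample's call set.

    Returns a new :class:`SampleCallSet` (input is not mutated) and the drop
    accounting. Filtering is idempotent and the output is a subset of the
    input.
    """
    cfg = cfg or FilterConfig()
    stats = FilterStats(n_input=len(callset.calls))
    kept = {}
    for key, call in callset.calls.items():
        if cfg.require_biallelic and len(call.alt_alleles) != 1:
            stats.n_multiallelic += 1
            continue
        if not (cfg.min_depth <= call.depth <= cfg.max_depth):
            stats.n_depth += 1
            continue
        if call.genotype is Genotype.MISSING:
            stats.n_missing += 1
            continue
        if call.genotype is Genotype.HET:
            if cfg.drop_heterozygous:
                stats.n_heterozygous += 1
                continue
        kept[key] = call
    stats.n_retained = len(kept)
    out = SampleCallSet(
        sample_id=callset.sample_id,
        calls=kept,
        callable_size=callset.callable_size,
        role=callset.role,
    )
    return out, stats
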