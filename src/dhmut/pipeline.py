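"""End-to-end orchestration: simulate → filter → call → stats, with manifest.

The analysis half (:func:`analyze_callsets`) is independent of where the
call sets came from — simulator or VCFs on disk — and is what the CLI
subcommands and the recovery tests drive.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .caller import MutationRecord, ParentalBaseline, build_baseline, call_cohort
from .errors import ConfigError
from .filters import FilterConfig, FilterStats, filter_calls
from .io import GeneIntervals, Role, SampleCallSet
from .rounding import round2
from .spectrum import (
    FrequencyReport,
    SpectrumReport,
    compare_spectra,
    compute_frequency,
    mean_frequency,
    spectrum_summary,
    subtract_background,
)
from .simulate import SimulationConfig, SimulationResult, simulate, write_simulation

__all__ = ["AnalysisResult", "RunManifest", "analyze_callsets", "run_pipeline"]


@dataclass
class AnalysisResult:
    """Everything the analysis computes for one cohort."""

    filtered: dict[str, SampleCallSet]
    filter_stats: dict[str, FilterStats]
    baseline: ParentalBaseline
    mutations: dict[str, list[MutationRecord]]  # regenerated samples only
    reports: dict[str, FrequencyReport]
    spectra: dict[str, SpectrumReport]
    control_mean: float | None
    treated_mean: float | None
    induced_rate: float | None
    spectrum_comparison: pd.DataFrame | None

    def mutations_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": m.sample_id,
                "chromosome": m.chromosome,
                "position": m.position,
                "parental_base": m.parental_base,
                "mutant_base": m.mutant_base,
                "class": m.substitution_class.label,
                "in_gene_region": m.in_gene_region,
            }
            for recs in self.mutations.values()
            for m in recs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id", "chromosome", "position", "parental_base",
                "mutant_base", "class", "in_gene_region",
            ],
        ).sort_values(["sample_id", "chromosome", "position"], ignore_index=True)

    def frequency_frame(self) -> pd.DataFrame:
        rows = []
        for sample, rep in self.reports.items():
            rows.append(
                {
                    "sample_id": sample,
                    "n_mutations_genome": rep.n_mutations_genome,
                    "callable_size": rep.callable_size,
                    "ratio_genome": round2(rep.ratio_genome),
                    "n_mutations_gene": rep.n_mutations_gene,
                    "gene_region_size": rep.gene_region_size,
                    "ratio_gene": None if rep.ratio_gene is None else round2(rep.ratio_gene),
                }
            )
        return pd.DataFrame(rows)

    def spectrum_frame(self) -> pd.DataFrame:
        rows = []
        for sample, rep in self.spectra.items():
            row = {"sample_id": sample}
            row.update({cls.label: rep.counts[cls] for cls in rep.counts})
            row["total"] = rep.total
            row["gc_to_at_fraction"] = rep.gc_to_at_fraction
            rows.append(row)
        return pd.DataFrame(rows)


def analyze_callsets(
    callsets: Mapping[str, SampleCallSet],
    gene_intervals: GeneIntervals | None = None,
    filter_cfg: FilterConfig | None = None,
    require_parent_call: bool = False,
    het_vetoes: bool = False,
    permutation_seed: int = 0,
) -> AnalysisResult:
    """Filter, build the parental baseline, call mutations, compute stats.

    ``callsets`` must carry roles: at least one ``PARENT_SEED`` sample forms
    the baseline; ``REGENERATED_CONTROL`` and ``REGENERATED_TREATED`` samples
    form the cohort whose mutations are identified (uniqueness scoped to the
    regenerated cohort).
    """
    filter_cfg = filter_cfg or FilterConfig()
    filtered: dict[str, SampleCallSet] = {}
    stats: dict[str, FilterStats] = {}
    for sample, cs in callsets.items():
        filtered[sample], stats[sample] = filter_calls(cs, filter_cfg)

    parents = [cs for cs in filtered.values() if cs.role is Role.PARENT_SEED]
    if not parents:
        raise ConfigError("analysis requires at least one parent (seed-germinated) sample")
    baseline = build_baseline(parents, prefiltered=True)

    regenerated = [
        cs
        for cs in filtered.values()
        if cs.role in (Role.REGENERATED_CONTROL, Role.REGENERATED_TREATED)
    ]
    mutations = call_cohort(
        regenerated,
        baseline,
        gene_intervals=gene_intervals,
        require_parent_call=require_parent_call,
        het_vetoes=het_vetoes,
    )

    reports: dict[str, FrequencyReport] = {}
    spectra: dict[str, SpectrumReport] = {}
    for cs in regenerated:
        recs = mutations[cs.sample_id]
        if cs.callable_size > 0:
            reports[cs.sample_id] = compute_frequency(
                recs, cs.callable_size, gene_intervals, sample_id=cs.sample_id
            )
        spectra[cs.sample_id] = spectrum_summary(recs, sample_id=cs.sample_id)

    def _group(role: Role) -> list[str]:
        return [cs.sample_id for cs in regenerated if cs.role is role]

    controls = [reports[s] for s in _group(Role.REGENERATED_CONTROL) if s in reports]
    treated = [reports[s] for s in _group(Role.REGENERATED_TREATED) if s in reports]
    control_mean = mean_frequency(controls) if controls else None
    treated_mean = mean_frequency(treated) if treated else None
    induced = (
        subtract_background(treated_mean, control_mean)
        if control_mean is not None and treated_mean is not None
        else None
    )
    comparison = None
    ctrl_spec = [spectra[s] for s in _group(Role.REGENERATED_CONTROL)]
    trt_spec = [spectra[s] for s in _group(Role.REGENERATED_TREATED)]
    if ctrl_spec and trt_spec:
        comparison = compare_spectra(ctrl_spec, trt_spec, seed=permutation_seed)

    return AnalysisResult(
        filtered=filtered,
        filter_stats=stats,
        baseline=baseline,
        mutations=mutations,
        reports=reports,
        spectra=spectra,
        control_mean=control_mean,
        treated_mean=treated_mean,
        induced_rate=induced,
        spectrum_comparison=comparison,
    )


@dataclass
class RunManifest:
    """Reproducibility record of one end-to-end run."""

    tool_version: str
    seed: int
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)
    output_paths: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")

    def check(self) -> None:
        for name, p in self.output_paths.items():
            if not Path(p).exists():
                raise RuntimeError(f"manifest lists missing output {name}: {p}")
        for sample, counts in self.stage_counts.get("filter", {}).items():
            drops = (
                counts["multiallelic"] + counts["depth"] + counts["heterozygous"]
                + counts["missing"]
            )
            if drops + counts["retained"] != counts["input"]:
                raise RuntimeError(f"filter counts inconsistent for {sample}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path,
    filter_cfg: FilterConfig | None = None,
) -> tuple[AnalysisResult, RunManifest]:
    """Synthetic end-to-end run: simulate, write inputs, analyze, write results.

    Identical config (including seed) yields byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate(config)
    sim_paths = write_simulation(sim, outdir / "sim")
    gene_intervals = sim.genome.gene_intervals()
    result = analyze_callsets(
        sim.callsets,
        gene_intervals=gene_intervals,
        filter_cfg=filter_cfg,
        permutation_seed=config.rng_seed,
    )

    out_paths: dict[str, Path] = {}
    out_paths["mutations"] = outdir / "mutations.tsv"
    result.mutations_frame().to_csv(out_paths["mutations"], sep="\t", index=False)
    out_paths["frequency"] = outdir / "frequency.tsv"
    result.frequency_frame().to_csv(out_paths["frequency"], sep="\t", index=False)
    out_paths["spectrum"] = outdir / "spectrum.tsv"
    result.spectrum_frame().to_csv(out_paths["spectrum"], sep="\t", index=False)
    if result.spectrum_comparison is not None:
        out_paths["comparison"] = outdir / "spectrum_comparison.tsv"
        result.spectrum_comparison.to_csv(out_paths["comparison"], sep="\t")

    manifest = RunManifest(
        tool_version=__version__,
        seed=config.rng_seed,
        config={
            k: ({cls.label: p for cls, p in v.items()} if k == "somaclonal_spectrum" else v)
            for k, v in dataclasses.asdict(config).items()
        },
        input_digests={
            name: _sha256(p) for name, p in sim_paths.items() if p.is_file()
        },
        stage_counts={
            "simulated_calls": {s: len(cs) for s, cs in sim.callsets.items()},
            "filter": {s: st.as_dict() for s, st in result.filter_stats.items()},
            "mutations": {s: len(m) for s, m in result.mutations.items()},
        },
        output_paths={name: str(p) for name, p in {**sim_paths, **out_paths}.items()},
    )
    manifest.check()
    manifest.write(outdir / "manifest.json")
    return result, manifest
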