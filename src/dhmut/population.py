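"""Doubled-haploid line production tallies per genotype × EMS dose.

Summarizes how many DH lines each treatment produced and how many were
harvested (set seed), with per-row percentages displayed as integers and
genotype/overall percentages at two decimals — the precisions the field's
production tables conventionally use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .rounding import pct_int, round2

__all__ = ["TreatmentTally", "PopulationSummary", "summarize", "read_tally_table"]


@dataclass(frozen=True)
class TreatmentTally:
    """One genotype × EMS-dose production outcome."""

    genotype: str
    ems_dose: float  # mg/L
    n_dh_lines: int
    n_harvested: int

    def __post_init__(self) -> None:
        if self.ems_dose < 0:
            raise ValueError(f"ems_dose must be >= 0, got {self.ems_dose}")
        if not (0 <= self.n_harvested <= self.n_dh_lines):
            raise ValueError(
                f"need 0 <= n_harvested <= n_dh_lines, got {self.n_harvested}/{self.n_dh_lines}"
            )


@dataclass
class PopulationSummary:
    rows: pd.DataFrame  # genotype, ems_dose, n_dh_lines, n_harvested, pct_harvested
    genotype_totals: pd.DataFrame  # n_dh_lines, n_harvested, pct_harvested (2 dec)
    total_dh_lines: int
    total_harvested: int
    pct_harvested: float | None  # overall, 2 decimals


def summarize(tallies: Sequence[TreatmentTally]) -> PopulationSummary:
    """Tabulate per-row, per-genotype and overall production outcomes.

    Row percentages are 100 × harvested / lines displayed as integers
    (half-up); rows with zero lines report a missing percentage. Genotype and
    overall percentages display at two decimals.
    """
    if not tallies:
        raise ValueError("summarize requires at least one tally row")
    rows = pd.DataFrame(
        {
            "genotype": [t.genotype for t in tallies],
            "ems_dose": [t.ems_dose for t in tallies],
            "n_dh_lines": [t.n_dh_lines for t in tallies],
            "n_harvested": [t.n_harvested for t in tallies],
        }
    )
    rows["pct_harvested"] = [
        pct_int(100.0 * t.n_harvested / t.n_dh_lines) if t.n_dh_lines else None
        for t in tallies
    ]
    by_geno = rows.groupby("genotype", sort=False)[["n_dh_lines", "n_harvested"]].sum()
    by_geno["pct_harvested"] = [
        round2(100.0 * h / n) if n else None
        for n, h in zip(by_geno["n_dh_lines"], by_geno["n_harvested"])
    ]
    total_n = int(rows["n_dh_lines"].sum())
    total_h = int(rows["n_harvested"].sum())
    overall = round2(100.0 * total_h / total_n) if total_n else None
    return PopulationSummary(
        rows=rows,
        genotype_totals=by_geno,
        total_dh_lines=total_n,
        total_harvested=total_h,
        pct_harvested=overall,
    )


def read_tally_table(path: str | Path) -> list[TreatmentTally]:
    """Read a delimited tally table: genotype, ems_dose, n_dh_lines, n_harvested."""
    df = pd.read_csv(path, sep="\t")
    required = {"genotype", "ems_dose", "n_dh_lines", "n_harvested"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        TreatmentTally(
            genotype=str(r.genotype),
            ems_dose=float(r.ems_dose),
            n_dh_lines=int(r.n_dh_lines),
            n_harvested=int(r.n_harvested),
        )
        for r in df.itertuples()
    ]
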