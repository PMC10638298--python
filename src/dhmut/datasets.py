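"""Bundled published tables from the barley microspore-mutagenesis study.

Two small TSVs ship with the package:

* ``dh_line_tallies.tsv`` — DH-line production outcomes per genotype and EMS
  dose (number of DH lines, number harvested).
* ``wgs_sample_table.tsv`` — the whole-genome-sequenced subset: per-sample
  homozygous mutation counts, mapped-genome sizes (Gb) and printed per-Mb
  ratios, genome-wide and for the gene-coding region.

These carry the published numbers; the per-Mb arithmetic on them is
recomputed by this package, while the underlying sequencing data (deposited
externally) is not redistributed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .population import TreatmentTally, read_tally_table

__all__ = ["load_dh_line_tallies", "load_wgs_sample_table"]


def _data_path(name: str):
    return resources.files("dhmut.data").joinpath(name)


def load_dh_line_tallies() -> list[TreatmentTally]:
    """DH-line production tallies (genotype × EMS dose)."""
    with resources.as_file(_data_path("dh_line_tallies.tsv")) as p:
        return read_tally_table(p)


def load_wgs_sample_table() -> pd.DataFrame:
    """Per-sample sequencing summary of the mutant cohort.

    Columns: sample_id, genotype, tissue (seed|microspore), ems_dose (mg/L),
    clean_gb, mapped_gb, n_mut_genome, ratio_genome, n_mut_gene, ratio_gene.
    ``mapped_gb`` is the callable denominator in Gb as printed (3 significant
    figures); ratios are the printed per-Mb values.
    """
    with resources.as_file(_data_path("wgs_sample_table.tsv")) as p:
        return pd.read_csv(p, sep="\t")
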