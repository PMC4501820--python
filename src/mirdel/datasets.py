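"""Bundled published summary tables from the 22q11.2 iPSC-neuron miRNA study.

Two small tables ship with the package:

* the differential-expression summary (per-miRNA genomic coordinates, log2
  fold change with the *positive = lower in cases* sign convention, nominal
  and BH-adjusted p-values, direction of change in cases), and
* the subject cohort (age, sex, group) used to generate the iPSC lines.

They are inputs for re-filtering and validation: re-applying the study's DE
thresholds to the printed columns, testing deletion-region enrichment from
the printed coordinates, and recomputing the demographic statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Hemizygously deleted interval (hg19), ~3 Mb on chromosome 22 band q11.2.
DELETION_INTERVAL: tuple[str, int, int] = ("chr22", 18_500_000, 21_900_000)


def _load(name: str) -> pd.DataFrame:
    with resources.files("mirdel.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def study_de_table() -> pd.DataFrame:
    """Published DE summary: 45 miRNAs passing p<0.01 and >1.5-fold.

    Columns: ``mirna``, ``coordinates`` (comma-separated ``chrN:start_end``
    loci, 1-based inclusive), ``log2_fc`` (positive = reduced in deletion
    carriers), ``pvalue``, ``padj``, ``direction`` (down/up in cases).
    """
    return _load("de_table_22q11_neurons.tsv")


def study_cohort() -> pd.DataFrame:
    """Published cohort demographics: 6 controls, 6 deletion carriers."""
    return _load("cohort_22q11_neurons.tsv")


def parse_loci(coordinates: str) -> list[tuple[str, int, int]]:
    """Parse a comma-separated ``chrN:start_end`` locus list."""
    loci = []
    for token in str(coordinates).split(","):
        contig, _, span = token.strip().partition(":")
        lo, _, hi = span.partition("_")
        loci.append((contig, int(lo), int(hi)))
    return loci


def locus_midpoints(coordinates: str) -> list[tuple[str, float]]:
    """Midpoint of each annotated locus, used for region membership."""
    return [(c, (s + e) / 2.0) for c, s, e in parse_loci(coordinates)]
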