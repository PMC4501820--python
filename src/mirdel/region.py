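"""Deletion-region enrichment of differentially expressed miRNAs.

Among the expressed miRNAs on the deletion's chromosome, is nominal
differential expression over-represented inside the deleted interval?  The
test is Fisher's exact test on the 2x2 table (in-region / out-region) x
(DE / not DE), computed by exact hypergeometric enumeration.  Expression is
thresholded in RPM (reads per million assigned reads), and region
membership uses the midpoint of a miRNA's annotated locus, which avoids
edge-straddling ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RegionTest:
    """2x2 contingency cells and Fisher exact p-values."""

    in_de: int  # a: in-region, DE
    in_not: int  # b: in-region, not DE
    out_de: int  # c: out-region, DE
    out_not: int  # d: out-region, not DE
    p_one_sided: float = np.nan
    p_two_sided: float = np.nan
    expressed_threshold: float = 1.0

    @property
    def table(self) -> list[list[int]]:
        return [[self.in_de, self.in_not], [self.out_de, self.out_not]]


def expressed_filter(
    counts: pd.DataFrame,
    assigned_totals: pd.Series | None = None,
    rpm_threshold: float = 1.0,
) -> set[str]:
    """miRNAs whose mean RPM across samples reaches the threshold.

    RPM_i is the mean over samples of count_ij * 1e6 / assigned_total_j;
    the boundary (RPM exactly equal to the threshold) is included.
    """
    totals = assigned_totals if assigned_totals is not None else counts.sum(axis=0)
    totals = pd.Series(totals).reindex(counts.columns)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero assigned-read total for sample(s) {bad}")
    rpm = counts.mul(1e6).div(totals, axis=1).mean(axis=1)
    return set(rpm.index[rpm >= rpm_threshold])


def build_contingency(
    expressed: Iterable[str],
    de: Iterable[str],
    loci: Mapping[str, tuple[str, int, int]],
    deletion_interval: tuple[str, int, int],
) -> RegionTest:
    """2x2 table over expressed miRNAs on the deletion's contig.

    A miRNA is in-region iff the midpoint of its locus lies inside the
    1-based inclusive interval.  miRNAs without a locus on the contig are
    excluded from the table.
    """
    contig, lo, hi = deletion_interval
    de = set(de)
    a = b = c = d = 0
    for mid in set(expressed):
        if mid not in loci or loci[mid][0] != contig:
            continue
        _, s, e = loci[mid]
        inside = lo <= (s + e) / 2.0 <= hi
        if inside:
            a, b = (a + 1, b) if mid in de else (a, b + 1)
        else:
            c, d = (c + 1, d) if mid in de else (c, d + 1)
    return RegionTest(in_de=a, in_not=b, out_de=c, out_not=d)


def fisher_exact(table) -> tuple[float, float]:
    """Fisher's exact test by hypergeometric enumeration.

    With margins fixed, the in-region DE cell X follows a hypergeometric
    law; one-sided p = P(X >= a) (enrichment tail), two-sided p = sum of the
    probabilities of all outcomes no more likely than the observed one.
    Probabilities come from log-gamma based pmf evaluations, so large
    margins do not overflow.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be nonnegative")
    n_total = a + b + c + d
    n_de = a + c
    n_in = a + b
    if n_total == 0:
        return 1.0, 1.0
    lo = max(0, n_in + n_de - n_total)
    hi = min(n_in, n_de)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n_total, n_de, n_in)
    p_obs = pmf[a - lo]
    p_one = float(pmf[support >= a].sum())
    p_two = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(p_one, 1.0), min(p_two, 1.0)


def region_test(
    counts: pd.DataFrame,
    de: Iterable[str],
    loci: Mapping[str, tuple[str, int, int]],
    deletion_interval: tuple[str, int, int],
    assigned_totals: pd.Series | None = None,
    rpm_threshold: float = 1.0,
) -> RegionTest:
    """Expressed filter, contingency table and Fisher test in one call."""
    expressed = expressed_filter(counts, assigned_totals, rpm_threshold)
    result = build_contingency(expressed, de, loci, deletion_interval)
    result.p_one_sided, result.p_two_sided = fisher_exact(result.table)
    result.expressed_threshold = rpm_threshold
    return result
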