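"""Negative-binomial differential expression for miRNA count matrices.

The model is the standard one for RNA-seq counts: library depth enters
through median-of-ratios size factors, within-group variability through an
NB dispersion alpha (variance = mu + alpha * mu^2), and each miRNA is tested
with a Wald statistic on the log2 ratio of group means whose standard error
comes from the delta method under the fitted NB.  Dispersion is estimated
per miRNA by the method of moments and moderated toward a fitted
alpha(mu) = a1/mu + a0 trend (simple averaging).  The calling thresholds are
the study's: nominal significance at p < 0.01 with a fold change > 1.5, and
genome-wide significance at Benjamini-Hochberg FDR < 0.05.

Sign convention: log2 fold change is log2(control / case), so a positive
value means the miRNA is reduced in the case (deletion-carrier) group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_LN2_SQ = np.log(2.0) ** 2


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each miRNA with no zero count, compute the geometric mean across
    samples; a sample's factor is the median over those miRNAs of its count
    divided by the geometric mean.  Scaling a sample's counts by c scales
    its factor by c.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "no miRNA has positive counts in every sample; "
            "median-of-ratios size factors are undefined"
        )
    log_geomean = np.log(positive).mean(axis=1)
    ratios = np.exp(np.log(positive).sub(log_geomean, axis=0))
    return ratios.median(axis=0).rename("size_factor")


@dataclass
class DispersionEstimate:
    """Per-miRNA dispersions with the fitted alpha(mu) = a1/mu + a0 trend."""

    alpha: pd.Series  # final (moderated) per-miRNA dispersion
    alpha_mom: pd.Series  # raw method-of-moments estimates
    trend_a0: float
    trend_a1: float

    def trend(self, mu) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.clip(self.trend_a1 / np.asarray(mu, dtype=float) + self.trend_a0, 0.0, None)


def estimate_dispersion(norm_counts: pd.DataFrame, groups: pd.Series) -> DispersionEstimate:
    """Moment estimator with trend moderation.

    Per miRNA: alpha_mom = max(0, (pooled within-group variance - mu) / mu^2)
    with mu the overall normalized mean.  The trend is a least-squares fit of
    alpha_mom on 1/mu over miRNAs with positive alpha_mom and positive mean;
    the final alpha averages the per-miRNA estimate and the trend value.
    """
    groups = groups.reindex(norm_counts.columns)
    levels = groups.unique()
    if len(levels) != 2 or (groups.value_counts() < 2).any():
        raise ValueError("need exactly two groups with >= 2 samples each")
    mu = norm_counts.mean(axis=1)
    num = pd.Series(0.0, index=norm_counts.index)
    dof = 0
    for g in levels:
        sub = norm_counts.loc[:, groups == g]
        num += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
        dof += sub.shape[1] - 1
    pooled_var = num / dof

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = ((pooled_var - mu) / mu**2).clip(lower=0.0)
    alpha_mom[mu <= 0] = np.nan

    fit_mask = (alpha_mom > 0) & (mu > 0)
    if fit_mask.sum() >= 2:
        x = 1.0 / mu[fit_mask].to_numpy()
        y = alpha_mom[fit_mask].to_numpy()
        design = np.column_stack([x, np.ones_like(x)])
        (a1, a0), *_ = np.linalg.lstsq(design, y, rcond=None)
    else:  # degenerate input (e.g. all-Poisson tiny fixture): flat floor
        a1, a0 = 0.0, float(np.nanmean(alpha_mom)) if alpha_mom.notna().any() else 0.0
    est = DispersionEstimate(
        alpha=pd.Series(index=norm_counts.index, dtype=float),
        alpha_mom=alpha_mom,
        trend_a0=float(a0),
        trend_a1=float(a1),
    )
    trend_vals = pd.Series(est.trend(mu), index=norm_counts.index)
    final = 0.5 * (alpha_mom.fillna(trend_vals) + trend_vals)
    est.alpha = final.clip(lower=0.0).rename("alpha")
    return est


def nb_wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersion: pd.Series,
    groups: pd.Series,
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-miRNA Wald test on the log2 ratio of group means.

    log2FC = log2((m_control + eps) / (m_case + eps)) with eps = 0.5 applied
    only when a group mean is exactly zero.  The variance of a normalized
    group mean under NB(mu, alpha) with size factors s_j is
    (mu * sum_j 1/s_j) / n^2 + alpha * mu^2 / n, and the delta method maps
    it onto the log2 scale.  p-values are two-sided normal tails.
    """
    groups = groups.reindex(counts.columns)
    size_factors = size_factors.reindex(counts.columns)
    levels = list(pd.unique(groups))
    if control_label not in levels or len(levels) != 2:
        raise ValueError(f"groups must contain {control_label!r} and one other label")
    case_label = next(g for g in levels if g != control_label)

    norm = counts.div(size_factors, axis=1)
    out = pd.DataFrame(index=counts.index)
    means, var_means = {}, {}
    for label in (control_label, case_label):
        cols = groups == label
        n_g = int(cols.sum())
        m_g = norm.loc[:, cols].mean(axis=1)
        inv_s = float((1.0 / size_factors[cols]).sum())
        m_eff = m_g.where(m_g > 0, 0.5)  # variance floor for empty groups
        var_means[label] = m_eff * inv_s / n_g**2 + dispersion * m_eff**2 / n_g
        means[label] = m_g
    out["mean_control"] = means[control_label]
    out["mean_case"] = means[case_label]

    zero = (out["mean_control"] == 0) | (out["mean_case"] == 0)
    eps = np.where(zero, 0.5, 0.0)
    lfc = np.log2((out["mean_control"] + eps) / (out["mean_case"] + eps))
    var_lfc = (
        var_means[control_label] / (out["mean_control"] + eps) ** 2
        + var_means[case_label] / (out["mean_case"] + eps) ** 2
    ) / _LN2_SQ
    se = np.sqrt(var_lfc)
    z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    both_zero = (out["mean_control"] == 0) & (out["mean_case"] == 0)
    lfc[both_zero] = 0.0
    z[both_zero.to_numpy()] = 0.0
    p[both_zero.to_numpy()] = 1.0

    out["log2_fc"] = lfc
    out["stat"] = z
    out["pvalue"] = np.clip(p, 0.0, 1.0)
    return out


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the number of tests (defaults to the length of the vector; a
    larger m reproduces adjustment done within a longer, partially observed
    ranking).  Adjusted values are cumulative minima from the bottom of the
    ranking, capped at 1, and are monotone in p-rank.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(m) if m is not None else p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def solve_bh_m(pvalue: float, padj: float, rank: int = 1) -> float:
    """Number of tests implied by one (p, p_adj) pair at a known rank."""
    if pvalue <= 0 or padj <= 0:
        raise ValueError("need positive p and p_adj")
    return padj * rank / pvalue


def call_de(
    table: pd.DataFrame,
    p_cut: float = 0.01,
    fold_cut: float = 1.5,
    fdr_cut: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag DE miRNAs at the study thresholds and summarize the calls.

    ``nominal`` requires p < p_cut and 2^|log2FC| > fold_cut; ``genomewide``
    requires p_adj < fdr_cut.  Positive log2FC counts as down-regulated in
    cases.  Threshold arguments outside their domains are rejected.
    """
    if not (0 < p_cut <= 1 and 0 < fdr_cut <= 1):
        raise ValueError("p_cut and fdr_cut must lie in (0, 1]")
    if fold_cut < 1:
        raise ValueError("fold_cut must be >= 1")
    table = table.copy()
    if "padj" not in table.columns and "pvalue" in table.columns:
        table["padj"] = bh_adjust(table["pvalue"].to_numpy())
    table["nominal"] = (table["pvalue"] < p_cut) & (2.0 ** table["log2_fc"].abs() > fold_cut)
    table["genomewide"] = table["padj"] < fdr_cut
    summary = {
        "total": int(table["nominal"].sum()),
        "down": int((table["nominal"] & (table["log2_fc"] > 0)).sum()),
        "up": int((table["nominal"] & (table["log2_fc"] < 0)).sum()),
        "genomewide": int(table["genomewide"].sum()),
    }
    return table, summary


def qc_spearman(norm_counts: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Spearman correlation (average ranks on ties).

    Constant columns have undefined rank correlation and yield NaN against
    every other sample (diagonal stays 1).
    """
    if norm_counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(norm_counts.to_numpy(), axis=0).statistic
    if norm_counts.shape[1] == 2:  # scipy returns a scalar for two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    out = pd.DataFrame(rho, index=norm_counts.columns, columns=norm_counts.columns)
    np.fill_diagonal(out.to_numpy(), 1.0)
    return out


def run_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    control_label: str = "control",
    p_cut: float = 0.01,
    fold_cut: float = 1.5,
    fdr_cut: float = 0.05,
    drop_all_zero: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Counts matrix to flagged DE table in one call.

    miRNAs with zero counts in every sample are dropped before testing, so
    the BH correction uses m = number of miRNAs actually tested.
    """
    if drop_all_zero:
        counts = counts[(counts.sum(axis=1) > 0)]
    sf = size_factors_median_of_ratios(counts)
    norm = counts.div(sf, axis=1)
    disp = estimate_dispersion(norm, groups)
    table = nb_wald_test(counts, sf, disp.alpha, groups, control_label=control_label)
    table["padj"] = bh_adjust(table["pvalue"].to_numpy())
    return call_de(table, p_cut=p_cut, fold_cut=fold_cut, fdr_cut=fdr_cut)
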