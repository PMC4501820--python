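"""qPCR relative expression (2^-ΔΔCt) and cohort demographic statistics.

Each sample's target Ct (mean of replicate wells) is normalized against the
arithmetic mean Ct of two small-RNA normalizers (ΔCt); the group contrast
ΔΔCt is the difference of group-mean ΔCt values and the reported fold
change is 2^-ΔΔCt.  Per-sample folds (each sample's ΔCt referenced to the
reference-group mean) feed a pooled two-sample t-test, reported one- and
two-tailed.  Cohort summaries are per-group mean, sample SD (n-1) and sex
counts of the subject table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RelativeExpression:
    """2^-ΔΔCt result for one target assay."""

    target: str
    normalizers: tuple[str, ...]
    reference_group: str
    case_group: str
    delta_ct: pd.Series  # per-sample ΔCt
    per_sample_fold: pd.Series  # 2^-(ΔCt - mean ΔCt of reference group)
    delta_delta_ct: float
    fold: float
    t: float = np.nan
    df: int = 0
    p_two_tailed: float = np.nan
    p_one_tailed: float = np.nan
    group_sd_fold: dict = field(default_factory=dict)
    group_sd_delta_ct: dict = field(default_factory=dict)


def _mean_ct(measurements: pd.DataFrame, sample: str, assay: str) -> float:
    rows = measurements[(measurements["sample"] == sample) & (measurements["assay"] == assay)]
    if rows.empty:
        raise ValueError(f"sample {sample!r} has no Ct values for assay {assay!r}")
    return float(rows["ct"].mean())


def delta_delta_ct(
    measurements: pd.DataFrame,
    target: str,
    normalizers: tuple[str, ...] | list[str],
    reference_group: str = "control",
) -> RelativeExpression:
    """2^-ΔΔCt relative expression with multiple normalizer assays.

    ``measurements`` is long-format with columns sample, group, assay, ct
    (one row per replicate well).  Per sample: Ct = mean of replicates,
    ΔCt = Ct_target - mean(Ct_normalizers).  ΔΔCt = mean ΔCt(case) -
    mean ΔCt(reference); fold = 2^-ΔΔCt, so ΔΔCt = 0 gives fold 1 and
    swapping the groups inverts the fold exactly.
    """
    groups = measurements.drop_duplicates("sample").set_index("sample")["group"]
    labels = list(pd.unique(groups))
    if reference_group not in labels or len(labels) != 2:
        raise ValueError(f"need two groups including {reference_group!r}, got {labels}")
    case_group = next(g for g in labels if g != reference_group)

    delta = {}
    for sample in groups.index:
        ct_t = _mean_ct(measurements, sample, target)
        ct_n = [_mean_ct(measurements, sample, nrm) for nrm in normalizers]
        delta[sample] = ct_t - float(np.mean(ct_n))
    delta = pd.Series(delta, name="delta_ct")

    ref_mean = delta[groups == reference_group].mean()
    case_mean = delta[groups == case_group].mean()
    ddct = case_mean - ref_mean
    per_sample_fold = 2.0 ** -(delta - ref_mean)

    res = RelativeExpression(
        target=target,
        normalizers=tuple(normalizers),
        reference_group=reference_group,
        case_group=case_group,
        delta_ct=delta,
        per_sample_fold=per_sample_fold,
        delta_delta_ct=float(ddct),
        fold=float(2.0**-ddct),
    )
    a = per_sample_fold[groups == case_group].to_numpy()
    b = per_sample_fold[groups == reference_group].to_numpy()
    res.t, res.df, res.p_two_tailed = two_sample_ttest(a, b)
    # one-tailed in the observed direction, as validation figures report it
    res.p_one_tailed = res.p_two_tailed / 2.0
    for label in (reference_group, case_group):
        sel = groups == label
        res.group_sd_fold[label] = float(per_sample_fold[sel].std(ddof=1))
        res.group_sd_delta_ct[label] = float(delta[sel].std(ddof=1))
    return res


def two_sample_ttest(
    group_a,
    group_b,
    pooled: bool = True,
    two_tailed: bool = True,
) -> tuple[float, int, float]:
    """Student's two-sample t-test (pooled variance by default).

    Returns (t, df, p).  One-tailed p is half the two-tailed value for the
    observed direction (1 - p/2 if the difference points the other way).
    Zero pooled variance with equal means gives t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    diff = a.mean() - b.mean()
    if pooled:
        df = na + nb - 2
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:  # Welch
        va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
        se = math.sqrt(va + vb)
        df = int((va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))) if va + vb > 0 else na + nb - 2
    if se == 0:
        if diff == 0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / se
    p_two = 2.0 * stats.t.sf(abs(t), df)
    if two_tailed:
        return float(t), int(df), float(min(p_two, 1.0))
    p_one = stats.t.sf(t, df)  # H1: mean(a) > mean(b)
    return float(t), int(df), float(p_one)


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group age mean, sample SD (ddof=1), n and sex counts.

    Values are unrounded; presentation rounding (one decimal) is the
    caller's concern.  Single-subject groups report SD as NaN.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    if (table["age"] <= 0).any():
        raise ValueError("ages must be positive")
    rows = []
    for group, sub in table.groupby("group"):
        sexes = sub["sex"].value_counts().to_dict()
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "age_mean": float(sub["age"].mean()),
                "age_sd": float(sub["age"].std(ddof=1)) if len(sub) > 1 else np.nan,
                "n_female": int(sexes.get("F", 0)),
                "n_male": int(sexes.get("M", 0)),
            }
        )
    return pd.DataFrame(rows).set_index("group")
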