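"""Group-level statistics and expression corroboration.

CNV prevalence (chromosomes affected per tumor) is compared across
molecular groups with one-way ANOVA followed by Tukey's HSD for pairwise
comparisons; 0.05 is the reported significance threshold. Expression
corroboration flags an amplified gene in a sample when that sample is the
cohort maximum and exceeds the cohort median by more than twice the median
absolute deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class GroupStatsResult:
    group_summary: pd.DataFrame  # group, n, mean, sd
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    alpha: float = 0.05


def group_stats(
    values: Mapping[str, float], groups: Mapping[str, str], alpha: float = 0.05
) -> GroupStatsResult:
    """One-way ANOVA + Tukey HSD on per-sample values keyed by sample id.

    Requires >= 2 groups with >= 2 samples each. Identical data across all
    groups yields F = 0 and all pairwise nulls retained.
    """
    df = pd.DataFrame(
        {"value": pd.Series(values), "group": pd.Series(groups)}
    ).dropna()
    sizes = df.groupby("group").size()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError(
            f"need >= 2 groups with >= 2 samples each; got sizes {sizes.to_dict()}"
        )
    arrays = [sub["value"].to_numpy(float) for _, sub in df.groupby("group")]
    grand = df["value"].mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = len(arrays) - 1, len(df) - len(arrays)
    if ssb == 0.0:
        f_stat, p_val = 0.0, 1.0
    elif ssw == 0.0:
        f_stat, p_val = float("inf"), 0.0
    else:
        f_stat = (ssb / df_b) / (ssw / df_w)
        p_val = float(sps.f.sf(f_stat, df_b, df_w))
    summary = (
        df.groupby("group")["value"]
        .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    if ssw == 0.0 and ssb == 0.0:
        pairs = []
        names = sorted(sizes.index)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairs.append(dict(group1=names[i], group2=names[j],
                                  meandiff=0.0, p_adj=1.0, reject=False))
        tukey_df = pd.DataFrame(pairs)
    else:
        res = pairwise_tukeyhsd(df["value"].to_numpy(float), df["group"].to_numpy(), alpha=alpha)
        tukey_df = pd.DataFrame(
            res.summary().data[1:],
            columns=[c.strip() for c in res.summary().data[0]],
        ).rename(columns={"p-adj": "p_adj"})
    return GroupStatsResult(summary, float(f_stat), float(p_val), tukey_df, alpha)


def expression_corroboration(
    expression: pd.DataFrame,
    amplification_calls: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Check amplified (gene, sample) pairs against an expression matrix.

    ``expression`` is gene x sample of log2(norm counts + 1). A call is
    corroborated iff its sample holds the cohort maximum for the gene and
    exceeds the cohort median by > 2 x MAD; a non-maximal sample above that
    bar is reported as elevated-not-maximal. Missing genes produce a
    warning row with status 'gene_missing'.
    """
    rows = []
    for gene, sample in amplification_calls:
        if gene not in expression.index:
            rows.append(dict(gene=gene, sample_id=sample, status="gene_missing",
                             value=np.nan, cohort_median=np.nan, mad=np.nan))
            continue
        vals = expression.loc[gene].astype(float)
        med = float(vals.median())
        mad = float((vals - med).abs().median())
        if sample not in vals.index:
            rows.append(dict(gene=gene, sample_id=sample, status="sample_missing",
                             value=np.nan, cohort_median=med, mad=mad))
            continue
        v = float(vals[sample])
        above = v > med + 2 * mad
        is_max = v == float(vals.max())
        if above and is_max:
            status = "corroborated"
        elif above:
            status = "elevated_not_maximal"
        else:
            status = "not_corroborated"
        rows.append(dict(gene=gene, sample_id=sample, status=status,
                         value=v, cohort_median=med, mad=mad))
    return pd.DataFrame(rows, columns=["gene", "sample_id", "status", "value",
                                       "cohort_median", "mad"])
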