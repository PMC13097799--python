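"""Differential methylated-region statistics and bisulfite-style ratios."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

NEGLOG10_P_CAP = 320.0


def dmr_test(group_a: pd.DataFrame, group_b: pd.DataFrame, paired: bool = False,
             pseudocount: float = 1.0, use_log: bool = False) -> pd.DataFrame:
    """Per-region two-sided t-tests of CPM between two sample groups.

    ``group_a`` / ``group_b`` are regions x samples CPM matrices sharing an
    index (region names); by convention group A is the condition of interest
    (e.g. tumor).  Welch's t is used unpaired, the paired t when ``paired``
    (columns matched by position).  ``log2fc`` is the log2 ratio of group
    mean CPMs with a pseudocount; ``direction`` is ``hypo`` when group A has
    the higher depletion-design signal (log2fc > 0, i.e. less methylation)
    and ``hyper`` otherwise.  A region with zero variance in both groups and
    equal means gets t = 0, p = 1 by convention.  q is Benjamini-Hochberg
    across all tested regions.
    """
    if not group_a.index.equals(group_b.index):
        raise ValueError("group region indices differ")
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    if paired and group_a.shape[1] != group_b.shape[1]:
        raise ValueError("paired mode needs equally sized groups")
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    xa = np.log2(a + pseudocount) if use_log else a
    xb = np.log2(b + pseudocount) if use_log else b
    if paired:
        res = stats.ttest_rel(xa, xb, axis=1)
    else:
        res = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "region": group_a.index,
        "mean_cpm_a": mean_a,
        "mean_cpm_b": mean_b,
        "log2fc": log2fc,
        "t_stat": t,
        "p": p,
        "q": q,
        "direction": np.where(log2fc > 0, "hypo", "hyper"),
    }).reset_index(drop=True)


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (log2fc, -log10 p) table, sorted by |log2fc| then name.

    p = 0 is capped at -log10 p = 320 (documented convention).
    """
    out = results[["region", "log2fc", "p", "direction"]].copy()
    with np.errstate(divide="ignore"):
        y = -np.log10(out["p"].to_numpy(dtype=float))
    out["neg_log10_p"] = np.minimum(y, NEGLOG10_P_CAP)
    out["abs_log2fc"] = out["log2fc"].abs()
    out = out.sort_values(["abs_log2fc", "region"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    return out[["region", "log2fc", "neg_log10_p", "direction"]]


def abs_log2fc_compare(hypo: pd.DataFrame, hyper: pd.DataFrame):
    """Compare |log2fc| magnitude between hypo- and hypermethylated regions.

    Returns ``(hypo_abs, hyper_abs, p)`` with a two-sided Wilcoxon rank-sum
    (Mann-Whitney U) p-value; small sets (< 3) fall back to the exact
    enumeration with a warning.
    """
    if len(hypo) == 0 or len(hyper) == 0:
        raise ValueError("both region sets must be non-empty")
    x = hypo["log2fc"].abs().to_numpy(dtype=float)
    y = hyper["log2fc"].abs().to_numpy(dtype=float)
    method = "auto"
    if min(len(x), len(y)) < 3:
        log.warning("a set has fewer than 3 regions; using the exact rank-sum test")
        method = "exact"
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    return x, y, p


def methylation_ratio(unconverted: int, total: int) -> float:
    """Bisulfite methylation ratio: unconverted reads over total coverage.

    Zero coverage yields NaN (missing), never 0 by convention.
    """
    if total < 0 or unconverted < 0:
        raise ValueError("counts must be non-negative")
    if unconverted > total:
        raise ValueError(f"unconverted ({unconverted}) exceeds total ({total})")
    if total == 0:
        return float("nan")
    return unconverted / total
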